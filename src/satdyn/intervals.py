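"""Circular-interval arithmetic (0-based, half-open) shared by the repeat
scanner and the deletion-space combinatorics.

An interval on a circle of size L is (start, length) with 0 <= start < L and
0 < length <= L; it covers positions {(start + k) mod L : 0 <= k < length}.
"""

from __future__ import annotations

from typing import Iterable, List, Tuple

Interval = Tuple[int, int]  # (start, length)


def normalize(start: int, length: int, circle: int) -> Interval:
    if circle <= 0:
        raise ValueError("circle length must be positive")
    if not 0 < length <= circle:
        raise ValueError(f"interval length {length} invalid on circle of {circle}")
    return (start % circle, length)


def from_range(start: int, end: int, circle: int) -> Interval:
    """Interval covering [start, end) on the circle (wraps if end <= start)."""
    start %= circle
    end %= circle
    length = end - start if end > start else circle - start + end
    return normalize(start, length, circle)


def end_of(iv: Interval, circle: int) -> int:
    return (iv[0] + iv[1]) % circle


def positions(iv: Interval, circle: int) -> List[int]:
    return [(iv[0] + k) % circle for k in range(iv[1])]


def contains_position(iv: Interval, pos: int, circle: int) -> bool:
    return (pos - iv[0]) % circle < iv[1]


def contains_interval(outer: Interval, inner: Interval, circle: int) -> bool:
    """Whether ``outer`` covers every position of ``inner``."""
    if outer[1] >= circle:
        return True
    if inner[1] > outer[1]:
        return False
    off = (inner[0] - outer[0]) % circle
    return off + inner[1] <= outer[1]


def overlaps(a: Interval, b: Interval, circle: int) -> bool:
    if a[1] >= circle or b[1] >= circle:
        return True
    off = (b[0] - a[0]) % circle
    if off < a[1]:
        return True
    off = (a[0] - b[0]) % circle
    return off < b[1]


def overlap_length(a: Interval, b: Interval, circle: int) -> int:
    """Number of circle positions covered by both intervals."""
    return sum(
        1 for p in positions(a, circle) if contains_position(b, p, circle)
    )


def contained_in_set(iv: Interval, regions: Iterable[Interval], circle: int) -> bool:
    """Whether ``iv`` lies entirely within the union of ``regions``.

    Exact for the common case of disjoint regions; handles touching regions
    by position-level checking for short intervals.
    """
    regions = list(regions)
    if any(contains_interval(r, iv, circle) for r in regions):
        return True
    return all(
        any(contains_position(r, p, circle) for r in regions)
        for p in positions(iv, circle)
    )
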