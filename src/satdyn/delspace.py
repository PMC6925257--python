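"""Deletion-opportunity combinatorics on an annotated circular plasmid.

A single deletion turns the full-length plasmid into either a *satellite
plasmid* (SP: keeps the replication origin but loses the marker, the
accessory genes and at least part of a replication gene — nonautonomous) or
an *accessory-gene deletion plasmid* (DP: keeps the entire backbone from the
origin through the marker intact and clips only accessory sequence).  The
number of (start, end) base-pair coordinate combinations admitting each
outcome measures the mutational target size of each fate; their ratio is
the mutational bias toward satellite formation.

Coordinates are 0-based half-open on the circle; a deletion removes the arc
[start, end) (wrapping allowed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Sequence, Tuple


from . import intervals as iv
from .errors import InvalidStateError, UndefinedResultError

__all__ = [
    "ROLES",
    "Feature",
    "PlasmidMap",
    "DeletionInterval",
    "is_sp_deletion",
    "is_dp_deletion",
    "count_deletion_space",
    "sp_dp_rate_ratio",
    "endpoint_regions",
]

ROLES = ("origin", "rep_gene", "marker", "accessory", "other")


@dataclass(frozen=True)
class Feature:
    name: str
    role: str
    interval: Tuple[int, int]  # (start, length) on the circle

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise InvalidStateError(f"unknown feature role {self.role!r}")


@dataclass(frozen=True)
class PlasmidMap:
    """Circular replicon with role-tagged feature intervals."""

    length: int
    features: Tuple[Feature, ...]

    def __post_init__(self) -> None:
        if self.length < 1:
            raise InvalidStateError("map length must be positive")
        for f in self.features:
            start, span = f.interval
            if not (0 <= start < self.length) or not (1 <= span <= self.length):
                raise InvalidStateError(
                    f"feature {f.name!r} interval {f.interval} outside circle"
                )

    def by_role(self, role: str) -> List[Feature]:
        return [f for f in self.features if f.role == role]

    def require_roles(self, roles: Sequence[str] = ("origin", "rep_gene", "marker", "accessory")) -> None:
        for role in roles:
            if not self.by_role(role):
                raise InvalidStateError(f"map has no feature with role {role!r}")


@dataclass(frozen=True)
class DeletionInterval:
    """The removed arc [start, end) of a candidate deletion."""

    start: int
    end: int

    def arc(self, circle: int) -> Tuple[int, int]:
        a = iv.from_range(self.start, self.end, circle)
        if a[1] >= circle:
            raise InvalidStateError("a deletion cannot remove the whole circle")
        return a


def is_sp_deletion(d: DeletionInterval, pmap: PlasmidMap) -> bool:
    """Satellite-forming deletion: removes every accessory and marker
    feature entirely, clips at least one base of a replication gene, and
    leaves every origin base intact."""
    L = pmap.length
    arc = d.arc(L)
    for f in pmap.by_role("accessory") + pmap.by_role("marker"):
        if not iv.contains_interval(arc, f.interval, L):
            return False
    if any(iv.overlaps(arc, f.interval, L) for f in pmap.by_role("origin")):
        return False
    return any(iv.overlaps(arc, f.interval, L) for f in pmap.by_role("rep_gene"))


def is_dp_deletion(d: DeletionInterval, pmap: PlasmidMap) -> bool:
    """Accessory-gene deletion: clips at least one base of every accessory
    feature while leaving the whole backbone (origin, replication genes,
    marker, and any other annotated backbone feature) untouched."""
    L = pmap.length
    arc = d.arc(L)
    accessory = pmap.by_role("accessory")
    if not accessory:
        return False
    for f in accessory:
        if not iv.overlaps(arc, f.interval, L):
            return False
    protected = [f for f in pmap.features if f.role != "accessory"]
    return not any(iv.overlaps(arc, f.interval, L) for f in protected)


# ----------------------------------------------------------------------
# Counting
# ----------------------------------------------------------------------

def _linearize(pmap: PlasmidMap) -> Tuple[int, int, Dict[str, List[Tuple[int, int]]]]:
    """Cut the circle at the (single) origin; return (cut, M, role->linear
    [start, end) intervals), where valid deletion endpoints live in [0, M]."""
    origins = pmap.by_role("origin")
    if len(origins) != 1:
        raise InvalidStateError("closed-form counting requires exactly one origin")
    L = pmap.length
    o_start, o_len = origins[0].interval
    cut = (o_start + o_len) % L  # first base after the origin
    M = L - o_len
    linear: Dict[str, List[Tuple[int, int]]] = {}
    for f in pmap.features:
        if f.role == "origin":
            continue
        x = (f.interval[0] - cut) % L
        end = x + f.interval[1]
        if end > M:
            raise InvalidStateError(
                f"feature {f.name!r} overlaps the origin; closed form unavailable"
            )
        linear.setdefault(f.role, []).append((x, end))
    return cut, M, linear


def _sp_geometry(pmap: PlasmidMap):
    """Linear geometry of SP-forming deletions around the required block."""
    cut, M, linear = _linearize(pmap)
    required = linear.get("accessory", []) + linear.get("marker", [])
    reps = linear.get("rep_gene", [])
    if not required or not reps:
        return cut, M, reps, 0, M + 1  # unsatisfiable: empty windows
    r_min = min(s for s, _ in required)
    r_max = max(e for _, e in required)
    return cut, M, reps, r_min, r_max


def _sp_count(pmap: PlasmidMap) -> int:
    """SP deletions: arc [s, e) contains the whole accessory+marker block
    (s <= r_min, e >= r_max), stays off the origin (guaranteed by the
    linearization), and clips >= 1 base of some rep gene.  The rep condition
    is a union over rep genes, which may sit on either side of the block."""
    cut, M, reps, r_min, r_max = _sp_geometry(pmap)
    ns = r_min + 1           # s in [0, r_min]
    ne = M - r_max + 1       # e in [r_max, M]
    if ns <= 0 or ne <= 0 or not reps:
        return 0
    if any(re > r_min and rs < r_max for rs, re in reps):
        return ns * ne       # such a rep gene is clipped by every valid arc
    before = [re for rs, re in reps if re <= r_min]
    after = [rs for rs, re in reps if rs >= r_max]
    # pairs violating every rep condition: s past every upstream rep gene
    # and e short of every downstream one
    bad_s = ns if not before else max(0, r_min - max(before) + 1)
    bad_e = ne if not after else max(0, min(after) - r_max + 1)
    return ns * ne - bad_s * bad_e


def _sp_ranges(pmap: PlasmidMap) -> Tuple[Tuple[int, int], Tuple[int, int], int]:
    """Inclusive linear endpoint windows of SP-forming deletions (positions
    that participate in at least one valid (s, e) pair), plus the cut."""
    cut, M, reps, r_min, r_max = _sp_geometry(pmap)
    if _sp_count(pmap) == 0:
        return (0, -1), (0, -1), cut
    s_hi, e_lo = r_min, r_max
    if not any(re > r_min and rs < r_max for rs, re in reps):
        after = [rs for rs, re in reps if rs >= r_max]
        before = [re for rs, re in reps if re <= r_min]
        if not after:        # rep genes only upstream: s must reach into one
            s_hi = min(r_min, max(before) - 1)
        if not before:       # rep genes only downstream: e must reach into one
            e_lo = max(r_max, min(after) + 1)
    return (0, s_hi), (e_lo, M), cut


def _dp_ranges(pmap: PlasmidMap) -> Tuple[Tuple[int, int], Tuple[int, int], int]:
    """Closed-form DP endpoint windows (inclusive, linear), and the cut."""
    cut, M, linear = _linearize(pmap)
    acc = sorted(linear.get("accessory", []))
    if not acc:
        return (0, -1), (0, -1), cut
    first_end = min(e for _, e in acc)
    last_start = max(s for s, _ in acc)
    a_lo = min(s for s, _ in acc)
    a_hi = max(e for _, e in acc)
    z0, z1 = 0, M
    for role, ivs in linear.items():
        if role == "accessory":
            continue
        for s, e in ivs:
            if e <= a_lo:
                z0 = max(z0, e)
            elif s >= a_hi:
                z1 = min(z1, s)
            else:
                return (0, -1), (0, -1), cut  # backbone feature inside the cluster
    return (z0, first_end - 1), (last_start + 1, z1), cut


def _count_from_ranges(
    s_range: Tuple[int, int], e_range: Tuple[int, int]
) -> int:
    s_lo, s_hi = s_range
    e_lo, e_hi = e_range
    ns = max(0, s_hi - s_lo + 1)
    ne = max(0, e_hi - e_lo + 1)
    total = ns * ne
    # subtract degenerate pairs with s >= e (arc would wrap through the origin)
    overlap_lo = max(s_lo, e_lo)
    overlap_hi = min(s_hi, e_hi)
    if overlap_hi >= overlap_lo:
        for s in range(overlap_lo, s_hi + 1):
            total -= max(0, min(s, e_hi) - e_lo + 1)
    return total


def count_deletion_space(
    pmap: PlasmidMap,
    classifier: str | Callable[[DeletionInterval, PlasmidMap], bool],
) -> int:
    """Number of (start, end) base combinations whose deletion fits a class.

    ``classifier`` is "sp", "dp", or any predicate ``f(DeletionInterval,
    PlasmidMap) -> bool``.  The named classes are counted in closed form
    from region boundaries (single-origin maps); arbitrary predicates are
    counted by exhaustive enumeration of all O(L^2) arcs.
    """
    if classifier == "sp":
        return _sp_count(pmap)
    if classifier == "dp":
        s_range, e_range, _ = _dp_ranges(pmap)
        return _count_from_ranges(s_range, e_range)
    if not callable(classifier):
        raise InvalidStateError(f"unknown deletion class {classifier!r}")
    L = pmap.length
    n = 0
    for start in range(L):
        for end in range(L):
            if start == end:
                continue
            if classifier(DeletionInterval(start, end), pmap):
                n += 1
    return n


def sp_dp_rate_ratio(pmap: PlasmidMap) -> float:
    """How many times more numerous SP-forming deletions are than DP-forming.

    Raises if the map admits no DP-forming deletion at all.
    """
    dp = count_deletion_space(pmap, "dp")
    if dp == 0:
        raise UndefinedResultError("no deletion can form a deletion plasmid on this map")
    return count_deletion_space(pmap, "sp") / dp


def endpoint_regions(pmap: PlasmidMap) -> Dict[str, Dict[str, Tuple[int, int]]]:
    """Circular intervals containing the valid deletion endpoints per class.

    Returns {"sp": {"start": (pos, span), "end": ...}, "dp": {...}} with
    (start, span) intervals on the circle, suitable for cross-region repeat
    counting and BED-like export.  Classes with no valid deletions are
    omitted.
    """
    L = pmap.length
    out: Dict[str, Dict[str, Tuple[int, int]]] = {}
    for name, fn in (("sp", _sp_ranges), ("dp", _dp_ranges)):
        (s_lo, s_hi), (e_lo, e_hi), cut = fn(pmap)
        if s_hi < s_lo or e_hi < e_lo:
            continue
        out[name] = {
            "start": iv.normalize(cut + s_lo, s_hi - s_lo + 1, L),
            "end": iv.normalize(cut + e_lo, e_hi - e_lo + 1, L),
        }
    return out
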