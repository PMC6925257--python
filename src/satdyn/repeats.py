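"""Near-perfect direct-repeat (microhomology) enumeration on circular DNA.

Short direct repeats can mediate RecA-independent deletions: single-strand
annealing between two nearby copies of a 7-15 bp near-repeat loops out the
intervening segment, leaving one copy at the deletion junction.  This module
enumerates every maximal pair of loci on a circular replicon whose best
gapped alignment (band +/-1, honouring at most one indel) satisfies a set of
repeat-calling thresholds, resolves overlapping calls, counts repeats able
to mediate deletions between two endpoint regions, and annotates observed
deletion junctions with their flanking homology.

Alignment model
---------------
A candidate is a pair of loci aligned column by column with at most
``max_indels`` (default 1) gap columns.  A column is a match only if both
bases are equal and not N.  Indel columns count toward the total mismatch
budget.  Identity is matches / alignment columns.  A reported match must
begin and end on match columns, satisfy all thresholds, and be *maximal*:
no other qualifying alignment contains both of its loci.  Coordinates are
0-based on the circle; loci may wrap the origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from . import intervals as iv
from .errors import InvalidStateError

__all__ = [
    "RepeatParams",
    "RepeatMatch",
    "enumerate_microhomologies",
    "resolve_overlaps",
    "count_cross_region_repeats",
    "annotate_junction_homology",
]

_ALPHABET = set(b"ACGTN")


@dataclass(frozen=True)
class RepeatParams:
    """Repeat-calling thresholds.

    Defaults follow the analysis of the study plasmid: repeats at least 7
    bases long, at most one inserted or deleted base, at most five total
    mismatches (indels included), at least 75% sequence identity.
    """

    min_length: int = 7
    max_indels: int = 1
    max_mismatches: int = 5
    min_identity: float = 0.75

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise InvalidStateError("min_length must be >= 1")
        if not 0.0 <= self.min_identity <= 1.0:
            raise InvalidStateError("min_identity must be in [0, 1]")
        if self.max_indels > self.max_mismatches:
            raise InvalidStateError("max_indels cannot exceed max_mismatches")
        if self.max_indels > 1:
            raise InvalidStateError("the banded (+/-1) aligner supports at most 1 indel")


@dataclass(frozen=True)
class RepeatMatch:
    """One near-perfect direct repeat: two loci plus alignment summary.

    Loci are (start, length) intervals on the circle, ordered by start
    position; ``n_mismatches`` includes indel columns.
    """

    locus_a: Tuple[int, int]
    locus_b: Tuple[int, int]
    alignment_length: int
    n_mismatches: int
    n_indels: int

    @property
    def identity(self) -> float:
        return (self.alignment_length - self.n_mismatches) / self.alignment_length

    def sort_key(self) -> Tuple:
        return (
            -self.alignment_length,
            self.n_mismatches,
            self.locus_a[0],
            self.locus_b[0],
            self.locus_a[1],
            self.locus_b[1],
        )


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper().encode()
    if not set(seq) <= _ALPHABET:
        bad = sorted(set(seq) - _ALPHABET)
        raise InvalidStateError(f"sequence contains non-ACGTN bytes: {bad}")
    return np.frombuffer(seq, dtype=np.uint8)


def _match_array(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Columnwise match flags; N (ASCII 78) never matches."""
    return (x == y) & (x != ord("N"))


def _candidates_on_diagonals(
    get_match: "callable",
    d_values: Iterable[int],
    d_neighbors: "callable",
    start_limit: int,
    maxspan: int,
    params: RepeatParams,
):
    """Yield raw alignment candidates (u, v, d, d2, mismatches).

    ``get_match(d)`` returns the boolean match array for offset ``d`` (index
    i aligns position i with i+d); ``d_neighbors(d)`` lists the offsets
    reachable by one indel.  Ungapped candidates are windows [u, v) on one
    diagonal; gapped candidates switch from diagonal d to d2 at one interior
    indel column.  Only inclusion-maximal, match-bounded windows per
    mismatch subset are generated; global maximality is enforced later.
    """
    min_len, max_mm, min_id = params.min_length, params.max_mismatches, params.min_identity
    match_cache: Dict[int, np.ndarray] = {}
    mism_cache: Dict[int, np.ndarray] = {}

    def mismatches(d: int) -> np.ndarray:
        if d not in mism_cache:
            m = get_match(d)
            match_cache[d] = m
            mism_cache[d] = np.flatnonzero(~m)
        return mism_cache[d]

    for d in d_values:
        P = mismatches(d)
        m = match_cache[d]
        lim = m.size
        if lim == 0:
            continue
        E = np.concatenate(([-1], P, [lim]))
        # ungapped: windows covering t consecutive mismatches, fully extended
        for t in range(0, min(max_mm, P.size) + 1):
            u = E[: E.size - t - 1] + 1
            v = E[t + 1 :]
            C = v - u
            ok = (C >= min_len) & (C <= maxspan) & (u < start_limit)
            if t > 0:
                first = P[:u.size]  # first covered mismatch per window
                last = P[t - 1 : t - 1 + u.size]
                ok &= (first > u) & (last < v - 1)
                ok &= (C - t) >= np.ceil(min_id * C) - 1e-9
                ok &= ((C - t) / np.maximum(C, 1)) >= min_id - 1e-12
            for uu, vv in zip(u[ok], v[ok]):
                yield int(uu), int(vv), d, d, t
        if params.max_indels < 1 or max_mm < 1:
            continue
        # gapped: prefix on d, one indel column, suffix on d2 = d +/- 1.
        # The indel column consumes one base of the longer locus only: for
        # d2 = d + 1 the extra base belongs to the second locus and the
        # suffix resumes at column p; for d2 = d - 1 the extra base is the
        # first locus's base at p and the suffix resumes at p + 1.
        for d2 in d_neighbors(d):
            P2 = mismatches(d2)
            m2 = match_cache[d2]
            lim2 = m2.size
            if lim2 == 0:
                continue
            sign = d2 - d
            events = np.union1d(P, P2)
            reps = np.unique(np.concatenate(([1], events + 1, events + 2)))
            reps = reps[(reps >= 1) & (reps < max(lim, lim2))]
            Ed = np.concatenate(([-1], P))
            Ed2 = np.concatenate((P2, [lim2]))
            j1 = np.searchsorted(P, reps)  # mismatches on d strictly before p
            suffix_start = reps if sign > 0 else reps + 1
            j2 = np.searchsorted(P2, suffix_start)
            for t1 in range(0, max_mm):
                for t2 in range(0, max_mm - t1):
                    sel = j1 >= t1  # enough prior mismatches to consume
                    if not sel.any():
                        continue
                    p = reps[sel]
                    ss = suffix_start[sel]
                    jj1, jj2 = j1[sel], j2[sel]
                    u = Ed[jj1 - t1] + 1
                    vi = jj2 + t2
                    good = vi < Ed2.size
                    if not good.any():
                        continue
                    p, ss, u, jj1, jj2, vi = (
                        p[good], ss[good], u[good], jj1[good], jj2[good], vi[good]
                    )
                    v = Ed2[vi]
                    len_a = v - u
                    len_b = len_a + sign
                    C = np.maximum(len_a, len_b)
                    t = t1 + t2 + 1
                    ok = (
                        (u < p)
                        & (v > ss)
                        & (u < start_limit)
                        & (C >= min_len)
                        & (len_a <= maxspan)
                        & (len_b <= maxspan)
                        & (len_b >= 1)
                        & (((C - t) / np.maximum(C, 1)) >= min_id - 1e-12)
                    )
                    if t1 > 0:
                        ok &= P[np.maximum(jj1 - t1, 0)] > u
                    if t2 > 0:
                        has = jj2 + t2 - 1 < P2.size
                        ok &= has
                        ok &= np.where(
                            has, P2[np.minimum(jj2 + t2 - 1, P2.size - 1)] < v - 1, False
                        )
                    for uu, vv in zip(u[ok], v[ok]):
                        yield int(uu), int(vv), d, d2, t


def _filter_maximal(records: List[RepeatMatch], circle: int) -> List[RepeatMatch]:
    """Drop matches whose loci are both contained in another match's loci."""
    records = sorted(set(records), key=lambda r: r.sort_key())
    if len(records) <= 1:
        return records
    a0 = np.array([r.locus_a[0] for r in records])
    al = np.array([r.locus_a[1] for r in records])
    b0 = np.array([r.locus_b[0] for r in records])
    bl = np.array([r.locus_b[1] for r in records])
    cc = np.array([r.alignment_length for r in records])

    def inside(x0, xl, y0, yl):
        # interval (x0, xl) contained in each (y0[i], yl[i])
        return ((x0 - y0) % circle) + xl <= yl

    out: List[RepeatMatch] = []
    for i, r in enumerate(records):
        ra0, ral = r.locus_a
        rb0, rbl = r.locus_b
        straight = inside(ra0, ral, a0, al) & inside(rb0, rbl, b0, bl)
        crossed = inside(rb0, rbl, a0, al) & inside(ra0, ral, b0, bl)
        cont = (cc >= r.alignment_length) & (straight | crossed)
        cont &= ~((a0 == ra0) & (al == ral) & (b0 == rb0) & (bl == rbl))
        if not cont.any():
            out.append(r)
    return out


def _canonical(a: Tuple[int, int], b: Tuple[int, int]) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    return (a, b) if (a[0], a[1]) <= (b[0], b[1]) else (b, a)


def enumerate_microhomologies(
    sequence: str, params: RepeatParams | None = None
) -> List[RepeatMatch]:
    """All maximal near-perfect direct repeats on a circular sequence.

    The circle is scanned as a doubled linear string and candidate loci are
    deduplicated modulo the sequence length.  Tandem (adjacent, even
    overlapping) repeats are allowed as long as the two loci are not
    identical.  Returns matches sorted by (length desc, mismatches asc,
    position).
    """
    params = params or RepeatParams()
    L = len(sequence)
    if L < params.min_length:
        return []
    x = _encode(sequence)
    T = np.concatenate([x, x])
    maxspan = L - 1

    def get_match(d: int) -> np.ndarray:
        lim = min(2 * L - d, L + maxspan)
        idx = np.arange(lim)
        return _match_array(T[idx], T[idx + d])

    def neighbors(d: int) -> List[int]:
        out = []
        if d + 1 <= L - 1:
            out.append(d + 1)
        if d - 1 >= 1:
            out.append(d - 1)
        return out

    best: Dict[Tuple, RepeatMatch] = {}
    for u, v, d, d2, t in _candidates_on_diagonals(
        get_match, range(1, L), neighbors, L, maxspan, params
    ):
        len_a = v - u
        len_b = v - u + (d2 - d)
        locus_a = ((u) % L, len_a)
        locus_b = ((u + d) % L, len_b)
        if locus_a == locus_b:
            continue
        a, b = _canonical(locus_a, locus_b)
        C = max(len_a, len_b)
        rec = RepeatMatch(a, b, C, t, 0 if d2 == d else 1)
        key = (a, b)
        old = best.get(key)
        if old is None or rec.n_mismatches < old.n_mismatches:
            best[key] = rec
    return sorted(_filter_maximal(list(best.values()), L), key=lambda r: r.sort_key())


def resolve_overlaps(matches: Sequence[RepeatMatch], circle: int) -> List[RepeatMatch]:
    """Greedy overlap resolution: longer first, then fewer mismatches.

    A match is kept only if neither of its loci overlaps any locus of an
    already-kept match; the final tie-break (position) makes the output
    independent of input order.
    """
    kept: List[RepeatMatch] = []
    kept_loci: List[Tuple[int, int]] = []
    for m in sorted(matches, key=lambda r: r.sort_key()):
        if any(
            iv.overlaps(locus, k, circle)
            for locus in (m.locus_a, m.locus_b)
            for k in kept_loci
        ):
            continue
        kept.append(m)
        kept_loci.extend([m.locus_a, m.locus_b])
    return kept


def count_cross_region_repeats(
    matches: Sequence[RepeatMatch],
    region_start: Sequence[Tuple[int, int]],
    region_end: Sequence[Tuple[int, int]],
    circle: int,
) -> int:
    """Repeats with one locus inside each region: potential deletion mediators.

    A locus is "inside" a region set when it is entirely contained in it.
    Both orientations count (locus_a in the start regions and locus_b in the
    end regions, or vice versa).
    """
    if not region_start or not region_end:
        return 0
    n = 0
    for m in matches:
        a_in_s = iv.contained_in_set(m.locus_a, region_start, circle)
        b_in_s = iv.contained_in_set(m.locus_b, region_start, circle)
        a_in_e = iv.contained_in_set(m.locus_a, region_end, circle)
        b_in_e = iv.contained_in_set(m.locus_b, region_end, circle)
        if (a_in_s and b_in_e) or (b_in_s and a_in_e):
            n += 1
    return n


def annotate_junction_homology(
    sequence: str,
    deletion_start: int,
    deletion_end: int,
    params: RepeatParams | None = None,
    window: int = 20,
) -> Optional[RepeatMatch]:
    """Best qualifying repeat flanking an observed deletion's endpoints.

    Searches +/-``window`` bases around each endpoint of the removed arc
    [deletion_start, deletion_end) for a direct repeat with one locus near
    each endpoint; returns the best by (length desc, mismatches asc) or
    None.  Coordinates of the returned loci are on the full circle.
    """
    params = params or RepeatParams()
    L = len(sequence)
    x = _encode(sequence)
    T = np.concatenate([x, x])

    def circ_slice(start: int, length: int) -> np.ndarray:
        start %= L
        return T[start : start + length]

    wa0 = (deletion_start - window) % L
    wb0 = (deletion_end - window) % L
    A = circ_slice(wa0, 2 * window)
    B = circ_slice(wb0, 2 * window)
    nA, nB = A.size, B.size

    # offsets d align A[i] with B[i + d]; pack B after A in one axis.  When
    # the two windows overlap on the circle, diagonals whose circle-level
    # offset is zero compare positions with themselves; they carry no
    # repeat information and are masked out entirely.
    def get_match(dd: int) -> np.ndarray:
        d = dd - nA  # true offset into B, shifted to keep dd positive
        if (wb0 - wa0 + d) % L == 0:
            return np.zeros(0, dtype=bool)
        lo = max(0, -d)
        hi = min(nA, nB - d)
        if hi <= lo:
            return np.zeros(0, dtype=bool)
        out = np.zeros(hi, dtype=bool)
        out[lo:hi] = _match_array(A[lo:hi], B[lo + d : hi + d])
        return out

    def neighbors(dd: int) -> List[int]:
        return [v for v in (dd + 1, dd - 1) if 1 <= v <= 2 * nA]

    best: Optional[RepeatMatch] = None
    maxspan = min(max(nA, nB), L - 1)
    for u, v, dd, dd2, t in _candidates_on_diagonals(
        get_match, range(max(1, nA - nB + 1), nA + nB), neighbors, nA, maxspan, params
    ):
        d = dd - nA
        d2 = dd2 - nA
        len_a, len_b = v - u, v - u + (d2 - d)
        if u + d < 0 or len_b < 1:
            continue
        locus_a = ((wa0 + u) % L, len_a)
        locus_b = ((wb0 + u + d) % L, len_b)
        if locus_a == locus_b:
            continue
        C = max(len_a, len_b)
        rec = RepeatMatch(*_canonical(locus_a, locus_b), C, t, 0 if d2 == d else 1)
        if best is None or rec.sort_key() < best.sort_key():
            best = rec
    return best
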