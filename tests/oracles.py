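"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration, structured
differently from the package implementations: the repeat oracle aligns every
anchored locus pair directly (instead of scanning diagonals of a doubled
string), the urn oracle enumerates every template-draw sequence, and the
deletion-space oracle classifies arcs through explicit position sets.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from typing import Dict, Sequence, Set, Tuple


# ----------------------------------------------------------------------
# Repeat scanning oracle
# ----------------------------------------------------------------------

def _pos_set(start: int, length: int, L: int) -> frozenset:
    return frozenset((start + k) % L for k in range(length))


def _canon(a: Tuple[int, int], b: Tuple[int, int], L: int):
    a = (a[0] % L, a[1])
    b = (b[0] % L, b[1])
    return (a, b) if a <= b else (b, a)


def brute_force_repeats(sequence: str, params) -> Set[Tuple]:
    """All maximal qualifying direct-repeat loci pairs, by exhaustive
    anchored banded alignment of every ordered start pair.

    Every qualifying alignment begins on a match column at its anchor
    (i, j), so enumerating all anchors with all column counts covers every
    candidate.  Returns canonical records
    (locus_a, locus_b, columns, mismatches, indels).
    """
    s = sequence.upper()
    L = len(s)
    min_len, max_mm, min_id = params.min_length, params.max_mismatches, params.min_identity
    allow_indel = params.max_indels >= 1
    span = L - 1

    def is_match(p: int, q: int) -> bool:
        a, b = s[p % L], s[q % L]
        return a == b and a != "N"

    candidates: Dict[Tuple, int] = {}
    for i in range(L):
        for j in range(L):
            if i == j or not is_match(i, j):
                continue  # all alignments are anchored on a match column
            # grow the band diagonals until no budget can survive
            mm0, mm1 = [], []
            pre0, pre1, premin = [0], [0], [0]
            while len(mm0) < span:
                k = len(mm0)
                a0 = 0 if is_match(i + k, j + k) else 1
                a1 = 0 if (allow_indel and is_match(i + k, j + k + 1)) else 1
                mm0.append(a0)
                mm1.append(a1)
                pre0.append(pre0[-1] + a0)
                pre1.append(pre1[-1] + a1)
                premin.append(premin[-1] + min(a0, a1))
                if pre0[-1] > max_mm and premin[-1] + 1 > max_mm:
                    break
            max_c = len(mm0)
            # ungapped alignments: columns C on the main diagonal
            for C in range(min_len, max_c + 1):
                t = pre0[C]
                if t > max_mm:
                    break
                if mm0[C - 1]:
                    continue  # must end on a match
                if (C - t) / C < min_id - 1e-12:
                    continue
                key = _canon((i, C), (j, C), L) + (C, 0)
                if key[0] == key[1]:
                    continue
                old = candidates.get(key)
                if old is None or t < old:
                    candidates[key] = t
            # one-indel alignments: locus at j is one base longer.  The
            # shifted diagonal compares i+k with j+k+1, which degenerates to
            # self-comparison when j+1 == i on the circle; such "alignments"
            # match the whole circle against itself and are not repeats.
            if allow_indel and (j - i) % L != L - 1:
                for la in range(2, max_c):
                    C = la + 1
                    if C < min_len:
                        continue
                    if premin[la] + 1 > max_mm:
                        break
                    if not is_match(i + la - 1, j + la):
                        continue  # last column (shifted diagonal) must match
                    best = min(
                        pre0[p] + 1 + (pre1[la] - pre1[p]) for p in range(1, C - 1)
                    )
                    if best > max_mm or (C - best) / C < min_id - 1e-12:
                        continue
                    key = _canon((i, la), (j, la + 1), L) + (C, 1)
                    old = candidates.get(key)
                    if old is None or best < old:
                        candidates[key] = best

    records = [(a, b, C, t, ind) for (a, b, C, ind), t in candidates.items()]
    # maximality: drop records whose loci are both contained in another's
    out = set()
    possets = [(_pos_set(*r[0], L), _pos_set(*r[1], L)) for r in records]
    for idx, r in enumerate(records):
        pa, pb = possets[idx]
        contained = False
        for jdx, big in enumerate(records):
            if jdx == idx or (big[0], big[1]) == (r[0], r[1]):
                continue
            qa, qb = possets[jdx]
            if (pa <= qa and pb <= qb) or (pa <= qb and pb <= qa):
                contained = True
                break
        if not contained:
            out.add(r)
    return out


def package_repeats_as_records(matches) -> Set[Tuple]:
    return {
        (m.locus_a, m.locus_b, m.alignment_length, m.n_mismatches, m.n_indels)
        for m in matches
    }


# ----------------------------------------------------------------------
# Urn replication oracle: exact doubling distributions by enumeration
# ----------------------------------------------------------------------

def polya_doubling_distribution(counts: Sequence[int]) -> Dict[Tuple[int, ...], Fraction]:
    """Exact outcome distribution of doubling by sequential draws from the
    growing pool (each drawn template adds one copy of its species)."""
    counts = tuple(int(c) for c in counts)
    n = sum(counts)
    dist: Dict[Tuple[int, ...], Fraction] = {counts: Fraction(1)}
    for _ in range(n):
        nxt: Dict[Tuple[int, ...], Fraction] = {}
        for state, p in dist.items():
            tot = sum(state)
            for k, c in enumerate(state):
                if c == 0:
                    continue
                new = list(state)
                new[k] += 1
                key = tuple(new)
                nxt[key] = nxt.get(key, Fraction(0)) + p * Fraction(c, tot)
        dist = nxt
    return dist


def frozen_doubling_distribution(counts: Sequence[int]) -> Dict[Tuple[int, ...], Fraction]:
    """Exact doubling distribution for n draws from the frozen starting pool."""
    counts = tuple(int(c) for c in counts)
    n = sum(counts)
    k = len(counts)
    dist: Dict[Tuple[int, ...], Fraction] = {}
    for draws in itertools.product(range(k), repeat=n):
        p = Fraction(1)
        for d in draws:
            p *= Fraction(counts[d], n)
        if p == 0:
            continue
        new = list(counts)
        for d in draws:
            new[d] += 1
        key = tuple(new)
        dist[key] = dist.get(key, Fraction(0)) + p
    return dist


# ----------------------------------------------------------------------
# Deletion-space oracle: explicit position sets
# ----------------------------------------------------------------------

def brute_force_deletion_counts(pmap) -> Tuple[int, int]:
    """(SP count, DP count) over all ordered (start, end) arcs, classifying
    each arc through raw position-set logic."""
    L = pmap.length
    acc = [_pos_set(*f.interval, L) for f in pmap.features if f.role == "accessory"]
    marker = [_pos_set(*f.interval, L) for f in pmap.features if f.role == "marker"]
    origin = [_pos_set(*f.interval, L) for f in pmap.features if f.role == "origin"]
    reps = [_pos_set(*f.interval, L) for f in pmap.features if f.role == "rep_gene"]
    others = [_pos_set(*f.interval, L) for f in pmap.features if f.role == "other"]
    sp = dp = 0
    for start in range(L):
        for end in range(L):
            if start == end:
                continue
            if end > start:
                arc = frozenset(range(start, end))
            else:
                arc = frozenset(range(start, L)) | frozenset(range(0, end))
            if (
                all(ps <= arc for ps in acc + marker)
                and not any(arc & ps for ps in origin)
                and any(arc & ps for ps in reps)
            ):
                sp += 1
            if (
                acc
                and all(arc & ps for ps in acc)
                and not any(arc & ps for ps in origin + reps + marker + others)
            ):
                dp += 1
    return sp, dp
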