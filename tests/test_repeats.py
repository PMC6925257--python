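"""Microhomology scanner: planted repeats, thresholds, overlap resolution,
junction annotation, and equivalence with the exhaustive-alignment oracle."""

import numpy as np
import pytest

from oracles import brute_force_repeats, package_repeats_as_records
from satdyn import intervals as iv
from satdyn.errors import InvalidStateError
from satdyn.repeats import (
    RepeatMatch,
    RepeatParams,
    annotate_junction_homology,
    count_cross_region_repeats,
    enumerate_microhomologies,
    resolve_overlaps,
)
from satdyn.synth import plant_repeat_pair, random_plasmid_sequence

# Designed circular fixtures (gap bases searched so that no incidental or
# extended alignment qualifies besides the intended one).
EXACT7 = "GTGGTTGAAATTGTGGTTGCGGCA"              # one exact 7-mer pair (0,7)/(12,7)
EIGHT_2MM = "CCAAGCTCATATCCCTAGTTCTCCGA"          # 8 cols, 2 subs, identity 0.75
EIGHT_3MM = "TGAACAGATCTCCTAAGCATAGTTGA"          # 8 cols, 3 subs: nothing qualifies
TWELVE_BOUNDARY = "TGGACGTAACCAGCGTTTGTACGCTATCCGGGCCC"  # 12 cols, 1 indel + 2 subs


def _covers(match: RepeatMatch, planted: RepeatMatch, circle: int) -> bool:
    loci = (match.locus_a, match.locus_b)
    want = (planted.locus_a, planted.locus_b)
    return (
        iv.contains_interval(loci[0], want[0], circle)
        and iv.contains_interval(loci[1], want[1], circle)
    ) or (
        iv.contains_interval(loci[0], want[1], circle)
        and iv.contains_interval(loci[1], want[0], circle)
    )


class TestThresholds:
    def test_single_planted_exact_repeat_is_the_only_call(self):
        ms = enumerate_microhomologies(EXACT7)
        assert len(ms) == 1
        m = ms[0]
        assert (m.locus_a, m.locus_b) == ((0, 7), (12, 7))
        assert m.alignment_length == 7 and m.identity == 1.0

    def test_eight_columns_two_mismatches_retained_at_identity_boundary(self):
        ms = enumerate_microhomologies(EIGHT_2MM)
        assert len(ms) == 1
        m = ms[0]
        assert m.alignment_length == 8 and m.n_mismatches == 2
        assert m.identity == pytest.approx(0.75)

    def test_eight_columns_three_mismatches_rejected(self):
        # identity 5/8 = 0.625 < 0.75, and no sub-window qualifies either
        assert enumerate_microhomologies(EIGHT_3MM) == []

    def test_indel_counts_toward_mismatch_total_at_boundary(self):
        ms = enumerate_microhomologies(TWELVE_BOUNDARY)
        assert len(ms) == 1
        m = ms[0]
        assert m.alignment_length == 12
        assert m.n_mismatches == 3 and m.n_indels == 1
        assert m.identity == pytest.approx(9 / 12)

    def test_sequence_shorter_than_min_length_yields_nothing(self):
        assert enumerate_microhomologies("ACGTA") == []

    def test_non_nucleotide_input_rejected(self):
        with pytest.raises(InvalidStateError):
            enumerate_microhomologies("ACGTX" * 10)

    def test_n_bases_never_match(self):
        # two N-runs do not constitute a repeat
        s = "ACGTACC" + "N" * 8 + "GACCTAG" + "N" * 8
        for m in enumerate_microhomologies(s):
            assert "N" not in _slice(s, m.locus_a) or "N" not in _slice(s, m.locus_b)


def _slice(s, locus):
    start, span = locus
    doubled = s + s
    return doubled[start : start + span]


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed,length,gc", [
        (0, 120, 0.5), (1, 120, 0.5), (2, 100, 0.2), (3, 100, 0.5),
    ])
    def test_scanner_equals_exhaustive_alignment(self, seed, length, gc):
        s = random_plasmid_sequence(length, gc, seed)
        params = RepeatParams()
        assert package_repeats_as_records(
            enumerate_microhomologies(s, params)
        ) == brute_force_repeats(s, params)

    def test_rotation_permutes_coordinates_but_preserves_alignments(self):
        s = random_plasmid_sequence(100, 0.5, 17)
        base = sorted(
            (m.alignment_length, m.n_mismatches, round(m.identity, 6))
            for m in enumerate_microhomologies(s)
        )
        for k in (1, 37, 63):
            rot = s[k:] + s[:k]
            got = sorted(
                (m.alignment_length, m.n_mismatches, round(m.identity, 6))
                for m in enumerate_microhomologies(rot)
            )
            assert got == base

    def test_exact_seed_rate_within_poisson_sanity_bound(self):
        """Exact >= 7-mer repeat pairs on i.i.d. uniform sequence arise at
        about L^2/2 * 4^-7 per circle; the observed total over ten 150-base
        circles must stay within a generous Poisson envelope."""
        total = 0
        for seed in range(10):
            s = random_plasmid_sequence(150, 0.5, 300 + seed)
            total += sum(
                1 for m in enumerate_microhomologies(s)
                if m.n_mismatches == 0 and m.alignment_length >= 7
            )
        lam = 10 * (150 * 149 / 2) * 0.25 ** 7
        # maximal exact matches are slightly rarer than raw exact seeds
        assert total <= lam + 5 * np.sqrt(lam) + 5


class TestResolveOverlaps:
    def _m(self, a, b, C, t, ind=0):
        return RepeatMatch(a, b, C, t, ind)

    def test_disjoint_matches_all_kept(self):
        ms = [self._m((0, 7), (20, 7), 7, 0), self._m((40, 8), (60, 8), 8, 1)]
        assert len(resolve_overlaps(ms, 100)) == 2

    def test_longer_match_takes_precedence(self):
        long = self._m((0, 9), (30, 9), 9, 2)
        short = self._m((4, 7), (50, 7), 7, 0)  # overlaps the long one's locus
        kept = resolve_overlaps([short, long], 100)
        assert kept == [long]

    def test_fewer_mismatches_breaks_length_ties(self):
        clean = self._m((0, 8), (30, 8), 8, 1)
        dirty = self._m((2, 8), (60, 8), 8, 3)
        kept = resolve_overlaps([dirty, clean], 100)
        assert kept[0] == clean and dirty not in kept

    def test_output_independent_of_input_order(self):
        rng = np.random.default_rng(3)
        ms = [
            self._m((int(rng.integers(90)), 7 + int(rng.integers(4))),
                    (int(rng.integers(90)), 7), 7 + int(rng.integers(4)),
                    int(rng.integers(4)))
            for _ in range(20)
        ]
        ref = resolve_overlaps(ms, 120)
        for perm_seed in range(5):
            perm = list(ms)
            np.random.default_rng(perm_seed).shuffle(perm)
            assert resolve_overlaps(perm, 120) == ref

    def test_output_is_overlap_free_across_matches(self):
        # tandem repeats may self-overlap, but distinct kept matches never
        # share sequence
        s = random_plasmid_sequence(150, 0.5, 9)
        kept = resolve_overlaps(enumerate_microhomologies(s), 150)
        for i, m1 in enumerate(kept):
            for m2 in kept[i + 1 :]:
                for a in (m1.locus_a, m1.locus_b):
                    for b in (m2.locus_a, m2.locus_b):
                        assert not iv.overlaps(a, b, 150)


class TestCrossRegionCounts:
    def test_both_loci_in_same_region_not_counted(self):
        m = RepeatMatch((5, 7), (20, 7), 7, 0, 0)
        assert count_cross_region_repeats([m], [(0, 30)], [(50, 30)], 100) == 0

    def test_three_planted_cross_region_pairs(self):
        s = random_plasmid_sequence(200, 0.5, 73)
        for (pa, pb) in ((5, 105), (25, 125), (45, 145)):
            s, _ = plant_repeat_pair(s, 8, pa, pb, 0, 0, rng=2)
        ms = resolve_overlaps(enumerate_microhomologies(s), 200)
        assert count_cross_region_repeats(ms, [(0, 60)], [(100, 60)], 200) == 3

    def test_empty_regions_count_zero(self):
        m = RepeatMatch((5, 7), (60, 7), 7, 0, 0)
        assert count_cross_region_repeats([m], [], [(50, 30)], 100) == 0

    def test_counts_monotone_in_min_length(self):
        s = random_plasmid_sequence(300, 0.5, 21)
        prev = None
        for min_len in range(7, 16):
            ms = resolve_overlaps(
                enumerate_microhomologies(s, RepeatParams(min_length=min_len)), 300
            )
            n = count_cross_region_repeats(ms, [(0, 120)], [(150, 120)], 300)
            if prev is not None:
                assert n <= prev
            prev = n


class TestJunctionAnnotation:
    def test_deletion_between_planted_copies_returns_the_repeat(self):
        # deletes the arc [7, 19): one copy of the repeat remains
        best = annotate_junction_homology(EXACT7, 7, 19)
        assert best is not None
        assert (best.locus_a, best.locus_b) == ((0, 7), (12, 7))
        assert best.alignment_length == 7 and best.identity == 1.0

    def test_repeat_free_circle_returns_none(self):
        assert annotate_junction_homology(EIGHT_3MM, 5, 15) is None

    def test_flanking_homology_covers_planted_copies(self):
        s = random_plasmid_sequence(120, 0.5, 4)
        s2, truth = plant_repeat_pair(s, 9, 20, 70, 0, 0, rng=1)
        best = annotate_junction_homology(s2, 29, 79)
        assert best is not None and _covers(best, truth, 120)

    def test_homology_outside_the_window_is_not_reported(self):
        s = random_plasmid_sequence(200, 0.5, 5)
        s2, truth = plant_repeat_pair(s, 10, 20, 120, 0, 0, rng=1)
        best = annotate_junction_homology(s2, 70, 170, window=15)
        if best is not None:
            assert not _covers(best, truth, 200)
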