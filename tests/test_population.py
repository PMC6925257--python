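"""Population layer: division rule, dilution, tuning, delay, establishment."""

import math

import numpy as np
import pytest
from scipy import stats

from satdyn._engine import TwoSpeciesModel
from satdyn.cell import (
    ANCESTRAL,
    DELETION,
    SATELLITE,
    CellState,
    FitnessModel,
    PlasmidSpecies,
    make_cell,
)
from satdyn.errors import InvalidStateError, NoEquilibriumError, UndefinedResultError
from satdyn.population import (
    FitnessTrajectory,
    PopulationEnsemble,
    SimulationConfig,
    advance_generation,
    crossover_generation,
    dilute,
    establishment_probability,
    realized_fitness,
    tune_background_fitness,
)

W_ANC = 1 - 18 * 0.0306  # model fitness of a pure full-length carrier


class TestAdvanceGeneration:
    def test_matched_fitness_doubles_exactly_at_single_substep(self):
        # w == w_b makes the division probability 1 at one sub-step
        cfg = SimulationConfig(background_fitness=W_ANC, division_substeps=1)
        pop = PopulationEnsemble({make_cell(n_ancestral=18): 500})
        out = advance_generation(pop, cfg, rng=0)
        assert out.n_cells == 1000

    def test_zero_fitness_cells_never_divide(self):
        heavy = CellState.from_counts(
            {make_cell(n_ancestral=18).species()[0]: 18}
        )
        cfg = SimulationConfig(
            background_fitness=1.0,
            fitness_model=FitnessModel(baseline=0.0),
        )
        pop = PopulationEnsemble({heavy: 100})
        out = advance_generation(pop, cfg, rng=0)
        assert out.n_cells == 100

    def test_mean_growth_factor_matches_doubling_rule(self):
        """Ancestral-only cells at w=0.4492 against a reference background
        grow by 2**0.4492 per generation in expectation."""
        cfg = SimulationConfig(background_fitness=1.0)
        pop = PopulationEnsemble({make_cell(n_ancestral=18): 10_000})
        out = advance_generation(pop, cfg, rng=1)
        factor = out.n_cells / 10_000
        assert factor == pytest.approx(2 ** W_ANC, rel=0.02)

    def test_empty_population_stays_empty(self):
        cfg = SimulationConfig()
        out = advance_generation(PopulationEnsemble({}), cfg, rng=0)
        assert out.n_cells == 0

    def test_nonviable_cells_removed_under_selection(self):
        cfg = SimulationConfig(selection_on=True, background_fitness=1.0)
        pop = PopulationEnsemble({make_cell(n_satellite=18): 50,
                                  make_cell(n_ancestral=18): 50})
        out = advance_generation(pop, cfg, rng=0)
        assert all(s.has_marker() for s in out.cells)


class TestDilute:
    def test_factor_one_is_identity(self):
        pop = PopulationEnsemble({make_cell(n_ancestral=18): 1234})
        assert dilute(pop, 1.0, rng=0).n_cells == 1234

    def test_binomial_thinning_moments(self):
        pop = PopulationEnsemble({make_cell(n_ancestral=18): 1_000_000})
        out = dilute(pop, 2000.0, rng=2)
        sd = math.sqrt(1_000_000 * (1 / 2000) * (1 - 1 / 2000))
        assert abs(out.n_cells - 500) < 5 * sd

    def test_single_cell_can_go_extinct(self):
        pop = PopulationEnsemble({make_cell(n_ancestral=18): 1})
        outcomes = {dilute(pop, 2000.0, np.random.default_rng(s)).n_cells
                    for s in range(300)}
        assert outcomes == {0}  # survival odds 1/2000: all thinned out here


class TestRealizedFitness:
    @pytest.mark.parametrize(
        "sizes, dilutions, gens, expected",
        [
            ([100, 100 * 2 ** 10], [1.0] * 10, 10, 1.0),
            ([500, 500], [1.0] * 10, 10, 0.0),
            ([100, 100 * 2 ** (0.9 * 8)], [1.0] * 8, 8, 0.9),
            ([1000, 1000], [2.0] * 4, 4, 1.0),  # constant size under 2-fold dilution
        ],
    )
    def test_definition(self, sizes, dilutions, gens, expected):
        assert realized_fitness(sizes, dilutions, gens) == pytest.approx(expected)

    def test_zero_initial_size_is_undefined(self):
        with pytest.raises(UndefinedResultError):
            realized_fitness([0, 100], [1.0], 5)


class TestEngineConsistency:
    """The aggregated multinomial sampler and the per-cell reference
    operations simulate the same process."""

    def test_aggregated_matches_cell_by_cell_distribution(self):
        cfg = SimulationConfig(background_fitness=0.77, division_substeps=2)
        model = TwoSpeciesModel()
        n_rep = 400
        seed_state = make_cell(n_ancestral=9, n_satellite=9)
        ref_tot, ref_anc = [], []
        rng = np.random.default_rng(5)
        for _ in range(n_rep):
            out = advance_generation(
                PopulationEnsemble({seed_state: 25}), cfg, rng
            )
            ref_tot.append(out.n_cells)
            ref_anc.append(sum(s.count_of(ANCESTRAL) * m for s, m in out.cells.items()))
        states = np.zeros((n_rep, 19), dtype=np.int64)
        states[:, 9] = 25
        got = model.advance(states, 0.77, np.random.default_rng(6), substeps=2)
        got_tot = got.sum(axis=1)
        got_anc = (got * np.arange(19)).sum(axis=1)
        assert stats.ks_2samp(ref_tot, got_tot).pvalue > 1e-3
        assert stats.ks_2samp(ref_anc, got_anc).pvalue > 1e-3

    def test_matched_fitness_population_is_martingale(self):
        """With w = w_b and 2-fold dilution per generation the focal size
        drifts by less than two standard errors over 10^3 replicates."""
        model = TwoSpeciesModel(cost_ancestral=0.0306, cost_mutant=0.0306,
                                mutant_lethal_without_ancestral=False)
        rng = np.random.default_rng(11)
        n0, gens = 64, 25
        states = np.zeros((1000, 19), dtype=np.int64)
        states[:, 18] = n0
        for _ in range(gens):
            states = model.advance(states, W_ANC, rng, substeps=4)
            states = model.dilute(states, 2.0, rng)
        final = states.sum(axis=1)
        se = final.std(ddof=1) / math.sqrt(len(final))
        assert abs(final.mean() - n0) < 2 * se + 1e-9


class TestTuning:
    desk = dict(n_cells=1500, n_replicates=3, burn_in_generations=60)

    def test_ancestral_only_equilibrium_is_cell_fitness(self):
        cfg = SimulationConfig(n_generations=200, seed=3)
        res = tune_background_fitness(make_cell(n_ancestral=18), cfg, **self.desk)
        assert res.background_fitness == pytest.approx(W_ANC, abs=0.01)

    def test_deletion_only_equilibrium(self):
        cfg = SimulationConfig(n_generations=200, seed=4)
        res = tune_background_fitness(make_cell(n_deletion=18), cfg, **self.desk)
        assert res.background_fitness == pytest.approx(0.910, abs=0.01)

    def test_reproducible_under_fixed_seed(self):
        cfg = SimulationConfig(n_generations=200, seed=9)
        r1 = tune_background_fitness(make_cell(n_ancestral=17, n_satellite=1),
                                     cfg, rng=42, **self.desk)
        r2 = tune_background_fitness(make_cell(n_ancestral=17, n_satellite=1),
                                     cfg, rng=42, **self.desk)
        assert r1.background_fitness == r2.background_fitness
        assert r1.n_iterations == r2.n_iterations

    def test_no_equilibrium_outside_bracket(self):
        cfg = SimulationConfig(n_generations=100, seed=5)
        with pytest.raises(NoEquilibriumError):
            tune_background_fitness(
                make_cell(n_ancestral=18), cfg,
                bracket=(0.9, 1.2), n_cells=500, n_replicates=2,
                burn_in_generations=20,
            )


class TestCrossover:
    @staticmethod
    def _traj(values):
        arr = np.asarray(values, dtype=float)
        g = np.arange(1, len(arr) + 1)
        return FitnessTrajectory(g, arr, arr, arr, 1)

    def test_identical_trajectories_cross_at_zero(self):
        t = self._traj([0.5, 0.6, 0.7])
        assert crossover_generation(t, t) == 0

    def test_strict_domination_runs_full_length(self):
        hi = self._traj([0.6, 0.7, 0.8])
        lo = self._traj([0.5, 0.6, 0.7])
        assert crossover_generation(hi, lo) == 3

    def test_first_non_exceedance_stops_the_count(self):
        sat = self._traj([0.6, 0.6, 0.5, 0.7])
        dele = self._traj([0.5, 0.5, 0.6, 0.6])
        assert crossover_generation(sat, dele) == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidStateError):
            crossover_generation(self._traj([1]), self._traj([1, 2]))


class TestEstablishment:
    cfg = SimulationConfig(
        dilution_factor=2000.0, generations_per_cycle=11,
        background_fitness=W_ANC, establishment_multiple=20.0,
    )

    def test_monotone_nonincreasing_in_mutant_cost(self):
        """A costlier mutant plasmid establishes no more often (checked at
        well-separated cost levels with paired trial counts)."""
        probs = []
        for i, cost in enumerate((0.0, 0.012, 0.0306)):
            mut = PlasmidSpecies(
                "mut", autonomous=True, carries_marker=True, per_copy_cost=cost
            )
            out = establishment_probability(mut, self.cfg, 30_000,
                                            rng=np.random.default_rng(100 + i))
            probs.append(out.probability)
        assert probs[0] >= probs[1] >= probs[2]

    def test_neutral_mutant_rarely_establishes(self):
        """A mutant costing exactly as much as the ancestral plasmid rides a
        critical lineage: dilution extinguishes nearly every founder."""
        neutral = PlasmidSpecies(
            "neutral", autonomous=True, carries_marker=True, per_copy_cost=0.0306
        )
        out = establishment_probability(neutral, self.cfg, 20_000, rng=7)
        assert 0.0 <= out.probability < 0.01

    def test_requires_at_least_one_trial(self):
        with pytest.raises(InvalidStateError):
            establishment_probability(SATELLITE, self.cfg, 0, rng=0)
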