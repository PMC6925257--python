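"""Vectorized two-species simulation kernels.

All three study protocols (background-fitness tuning, phenotypic delay,
establishment) involve cells carrying at most two plasmid species: the
ancestral full-length plasmid plus one mutant species (satellite or deletion
plasmid).  A newborn cell is then fully described by its ancestral copy
number ``a`` in 0..N (the mutant holds the remaining N - a copies), so a
population aggregates exactly into a length-(N+1) vector of cell counts.

The kernels here are exact samplers of the same process as the per-cell
operations in :mod:`satdyn.cell`:

* division of a cell in state ``a`` produces an (ordered) daughter pair
  ``(d1, d2)`` whose joint law is the replication scheme composed with the
  multivariate hypergeometric split of the doubled pool;
* for a batch of m dividing cells the pair outcomes are multinomial over the
  enumerable outcome space, which is sampled exactly whatever m is (this is
  what keeps 10^16-cell populations affordable);
* daughters without a marker-bearing plasmid are removed when selection is
  on (for a satellite mutant this is the ``a = 0`` state).

Division rule: one "generation" is one background doubling.  A cell of
fitness w facing a background of fitness w_b must multiply by 2**(w/w_b)
per generation in expectation for relative fitness to coincide with the
Malthusian-ratio definition used in competition assays.  Because that target
can exceed 2, the generation is split into S sub-steps in which each cell
divides with probability q = 2**((w/w_b)/S) - 1; the expected growth per
generation is then exactly 2**(w/w_b) for any S >= w/w_b.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import stats

__all__ = ["TwoSpeciesModel", "EstablishmentOutcome"]


def _pair_outcomes(
    a: int, n: int, scheme: str
) -> Tuple[np.ndarray, np.ndarray]:
    """Joint law of the ordered daughter pair for a parent in state ``a``.

    Returns (probs, contrib) where probs has one entry per outcome and
    contrib maps each outcome to its increment over the N+1 state bins
    (two daughters per outcome).
    """
    probs: List[float] = []
    contribs: List[np.ndarray] = []
    b = n - a
    if scheme == "copy_once":
        k_support = [(a, 1.0)]
    elif scheme == "polya":
        if a == 0 or b == 0:
            k_support = [(0, 1.0)] if a == 0 else [(n, 1.0)]
        else:
            kk = np.arange(n + 1)
            pk = stats.betabinom.pmf(kk, n, a, b)
            k_support = [(int(k), float(p)) for k, p in zip(kk, pk) if p > 0]
    elif scheme == "frozen":
        kk = np.arange(n + 1)
        pk = stats.binom.pmf(kk, n, a / n)
        k_support = [(int(k), float(p)) for k, p in zip(kk, pk) if p > 0]
    else:
        raise ValueError(f"unknown replication scheme {scheme!r}")
    for k, pk in k_support:
        pooled_a = a + k
        jj = np.arange(n + 1)
        pj = stats.hypergeom.pmf(jj, 2 * n, pooled_a, n)
        for j, p in zip(jj, pj):
            if p <= 0:
                continue
            d1, d2 = int(j), pooled_a - int(j)
            c = np.zeros(n + 1)
            c[d1] += 1
            c[d2] += 1
            probs.append(pk * p)
            contribs.append(c)
    probs_arr = np.asarray(probs)
    return probs_arr / probs_arr.sum(), np.asarray(contribs)


@dataclass
class TwoSpeciesModel:
    """Aggregated-state model for ancestral + one mutant plasmid species.

    Parameters
    ----------
    cost_ancestral, cost_mutant : float
        Additive per-copy fitness costs.
    mutant_lethal_without_ancestral : bool
        True for a satellite mutant under selection: cells whose last
        ancestral copy segregated away carry no marker and are removed.
        (They could not replicate either.)  False for a deletion mutant.
    copy_number : int
        Nominal plasmid copies per newborn cell.
    scheme : str
        Replication scheme; see :mod:`satdyn.cell`.
    """

    cost_ancestral: float = 0.0306
    cost_mutant: float = 0.0
    mutant_lethal_without_ancestral: bool = True
    copy_number: int = 18
    scheme: str = "copy_once"
    fitness_floor: float = 0.0

    _probs: List[np.ndarray] = field(init=False, repr=False)
    _contribs: List[np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = self.copy_number
        self._probs, self._contribs = [], []
        for a in range(n + 1):
            p, c = _pair_outcomes(a, n, self.scheme)
            if self.mutant_lethal_without_ancestral:
                # zero out dead daughters (a' = 0) in the contribution map
                c = c.copy()
                c[:, 0] = 0.0
            self._probs.append(p)
            self._contribs.append(c)

    # ------------------------------------------------------------------
    @property
    def fitness(self) -> np.ndarray:
        """Cell fitness per state a = 0..N."""
        a = np.arange(self.copy_number + 1)
        w = 1.0 - self.cost_ancestral * a - self.cost_mutant * (self.copy_number - a)
        return np.maximum(self.fitness_floor, w)

    def division_prob(self, background_fitness: float, substeps: int) -> np.ndarray:
        """Per-sub-step division probability per state, and the sub-step count."""
        r = self.fitness / background_fitness
        if self.mutant_lethal_without_ancestral:
            r = r.copy()
            r[0] = 0.0  # no machinery, no division
        return np.clip(2.0 ** (r / substeps) - 1.0, 0.0, 1.0)

    def min_substeps(self, background_fitness: float) -> int:
        return max(1, int(np.ceil(self.fitness.max() / background_fitness)))

    # ------------------------------------------------------------------
    def advance(
        self,
        states: np.ndarray,
        background_fitness: float,
        rng: np.random.Generator,
        substeps: int = 8,
    ) -> np.ndarray:
        """Advance populations by one background doubling (in place-safe).

        ``states`` is (n_pops, N+1) int64: cell counts per ancestral-copy
        state.  Exact sampling at any population size.
        """
        n = self.copy_number
        substeps = max(substeps, self.min_substeps(background_fitness))
        q = self.division_prob(background_fitness, substeps)
        states = states.astype(np.int64, copy=True)
        for _ in range(substeps):
            dividing = rng.binomial(states, q[None, :])
            new_states = states - dividing
            for a in range(n + 1):
                m = dividing[:, a]
                if not m.any():
                    continue
                outcomes = rng.multinomial(m, self._probs[a])
                daughters = outcomes @ self._contribs[a]
                new_states += np.rint(daughters).astype(np.int64)
            states = new_states
        return states

    def dilute(
        self, states: np.ndarray, factor: float, rng: np.random.Generator
    ) -> np.ndarray:
        """Binomial thinning: each cell survives with probability 1/factor."""
        if factor <= 1.0:
            return states.copy()
        return rng.binomial(states, 1.0 / factor)

    # ------------------------------------------------------------------
    def run_growth(
        self,
        states: np.ndarray,
        n_generations: int,
        background_fitness: float,
        dilution_factor: float,
        rng: np.random.Generator,
        substeps: int = 8,
        stop_above: Optional[float] = None,
        stop_below: Optional[float] = None,
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Serial-dilution growth; returns (final states, pre-dilution sizes).

        Sizes are recorded pre-dilution each generation, shape
        (n_pops, n_generations + 1) with column 0 the initial sizes.
        Early exit (for decisive bisection brackets) when every population's
        size leaves [stop_below, stop_above]; remaining columns repeat the
        last recorded value.
        """
        sizes = np.zeros((states.shape[0], n_generations + 1))
        sizes[:, 0] = states.sum(axis=1)
        for t in range(1, n_generations + 1):
            states = self.advance(states, background_fitness, rng, substeps)
            sizes[:, t] = states.sum(axis=1)
            if stop_above is not None:
                tot = sizes[:, t]
                if np.all((tot > stop_above) | (tot < stop_below)):
                    sizes[:, t + 1 :] = tot[:, None]
                    break
            states = self.dilute(states, dilution_factor, rng)
        return states, sizes


# ----------------------------------------------------------------------
# Establishment trials: many single-founder populations at once.
# ----------------------------------------------------------------------

@dataclass
class EstablishmentOutcome:
    n_trials: int
    n_established: int
    n_unresolved: int

    @property
    def probability(self) -> float:
        return self.n_established / self.n_trials

    def ci95(self) -> Tuple[float, float]:
        """Wilson score interval for the establishment probability."""
        n, k = self.n_trials, self.n_established
        if n == 0:
            return (0.0, 1.0)
        z = 1.959963984540054
        p = k / n
        denom = 1 + z * z / n
        centre = (p + z * z / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
        return (max(0.0, centre - half), min(1.0, centre + half))


def run_establishment_trials(
    model: TwoSpeciesModel,
    n_trials: int,
    background_fitness: float,
    rng: np.random.Generator,
    dilution_factor: float = 2000.0,
    generations_per_cycle: int = 11,
    establishment_multiple: float = 20.0,
    substeps: int = 8,
    founder_state: Optional[int] = None,
    aggregate_above: int = 192,
    max_cycles: int = 400,
    batch_size: int = 50_000,
) -> EstablishmentOutcome:
    """Single-founder establishment probability under daily serial transfer.

    Each trial seeds one newborn cell (1 mutant + N-1 ancestral copies) at a
    division sampled within a growth cycle with probability proportional to
    the number of divisions in each generation (2**g weighting), then follows
    the lineage through 1/dilution_factor daily bottlenecks until it either
    goes extinct or reaches establishment_multiple * dilution_factor cells at
    the end of a growth cycle.

    Trials are simulated cell-by-cell while small (exact pair sampling per
    division) and switch to the aggregated multinomial representation once
    they exceed ``aggregate_above`` cells.
    """
    n = model.copy_number
    founder = n - 1 if founder_state is None else founder_state
    threshold = establishment_multiple * dilution_factor
    substeps = max(substeps, model.min_substeps(background_fitness))
    q = model.division_prob(background_fitness, substeps)
    lethal = model.mutant_lethal_without_ancestral
    established = 0
    unresolved = 0

    # a founder arises at a division within the cycle; divisions in
    # generation g are 2**g as numerous as in generation 0
    origin_w = 2.0 ** np.arange(generations_per_cycle)
    origin_w /= origin_w.sum()

    done = 0
    while done < n_trials:
        batch = min(batch_size, n_trials - done)
        done += batch
        origin = rng.choice(generations_per_cycle, size=batch, p=origin_w)
        # generations of growth left before the founder's first transfer
        gens_left = (generations_per_cycle - 1 - origin).astype(np.int64)

        # cell-level representation: one row per cell, in small trials
        trial_of = np.arange(batch, dtype=np.int64)
        a_of = np.full(batch, founder, dtype=np.int64)
        # aggregated representation for trials that outgrew cell level
        agg_states = np.zeros((0, n + 1), dtype=np.int64)
        agg_trial = np.zeros(0, dtype=np.int64)

        for _step in range(max_cycles * (generations_per_cycle + 1)):
            if trial_of.size == 0 and agg_states.shape[0] == 0:
                break

            # --- transfer any trial whose countdown reached zero -------
            due_trial = gens_left == 0
            if due_trial.any():
                if agg_states.shape[0]:
                    due_agg = due_trial[agg_trial]
                    if due_agg.any():
                        sizes = agg_states.sum(axis=1)
                        est = due_agg & (sizes >= threshold)
                        established += int(est.sum())
                        thin = due_agg & ~est
                        if thin.any():
                            agg_states[thin] = rng.binomial(
                                agg_states[thin], 1.0 / dilution_factor
                            )
                        keep = ~est & (agg_states.sum(axis=1) > 0)
                        agg_states, agg_trial = agg_states[keep], agg_trial[keep]
                if trial_of.size:
                    due_cells = due_trial[trial_of]
                    surv = rng.random(trial_of.size) < (1.0 / dilution_factor)
                    keep = ~due_cells | surv
                    trial_of, a_of = trial_of[keep], a_of[keep]
                gens_left[due_trial] = generations_per_cycle

            # --- one generation of growth ------------------------------
            if trial_of.size:
                for _ in range(substeps):
                    div = rng.random(a_of.size) < q[a_of]
                    if div.any():
                        ad = a_of[div]
                        if model.scheme == "copy_once":
                            pooled_a = 2 * ad
                        else:
                            if model.scheme == "polya":
                                p = rng.beta(np.maximum(ad, 1e-9),
                                             np.maximum(n - ad, 1e-9))
                                p = np.where(ad == 0, 0.0, p)
                                p = np.where(ad == n, 1.0, p)
                            else:  # frozen
                                p = ad / n
                            pooled_a = ad + rng.binomial(n, p)
                        d1 = rng.hypergeometric(pooled_a, 2 * n - pooled_a, n)
                        d2 = pooled_a - d1
                        keep = ~div
                        a_of = np.concatenate([a_of[keep], d1, d2])
                        trial_of = np.concatenate(
                            [trial_of[keep], trial_of[div], trial_of[div]]
                        )
                        if lethal:
                            alive = a_of > 0
                            a_of, trial_of = a_of[alive], trial_of[alive]
            if agg_states.shape[0]:
                agg_states = model.advance(
                    agg_states, background_fitness, rng, substeps
                )
                alive = agg_states.sum(axis=1) > 0
                agg_states, agg_trial = agg_states[alive], agg_trial[alive]
            gens_left -= 1

            # --- promote big cell-level trials to aggregated -----------
            if trial_of.size:
                counts = np.bincount(trial_of, minlength=batch)
                big = counts > aggregate_above
                if big.any():
                    move = big[trial_of]
                    moved_t, moved_a = trial_of[move], a_of[move]
                    trial_of, a_of = trial_of[~move], a_of[~move]
                    big_ids = np.flatnonzero(big)
                    remap = np.zeros(batch, dtype=np.int64)
                    remap[big_ids] = np.arange(big_ids.size)
                    add = np.zeros((big_ids.size, n + 1), dtype=np.int64)
                    np.add.at(add, (remap[moved_t], moved_a), 1)
                    agg_states = np.vstack([agg_states, add])
                    agg_trial = np.concatenate([agg_trial, big_ids])
        else:
            unresolved += int(
                np.union1d(np.unique(trial_of), np.unique(agg_trial)).size
            )

    return EstablishmentOutcome(n_trials, established, unresolved)
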