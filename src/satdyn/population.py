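"""Population layer: serial-dilution competition against a fixed background.

A focal collection of plasmid-carrying cells competes against an implicit
background population of fixed relative fitness ``w_b``.  Time is measured
in background doublings ("generations").  Per generation each viable focal
cell must grow by ``2**(w/w_b)`` in expectation for relative fitness to be
the ratio of Malthusian parameters; the generation is therefore split into
sub-steps in which a cell divides with probability ``2**((w/w_b)/S) - 1``
(see :mod:`satdyn._engine`).  A dividing cell doubles its plasmids and
assorts them randomly but evenly to its daughters; daughters left without a
marker-bearing plasmid are removed when selection is on.

Three protocols are provided:

* :func:`tune_background_fitness` — bisect on ``w_b`` until the focal
  population is demographically stable under 2-fold serial dilution; the
  tuned ``w_b`` is the focal type's realized equilibrium fitness.
* :func:`phenotypic_delay_trajectories` — realized-fitness time series of
  populations founded by cells carrying a single new mutant plasmid.
* :func:`establishment_probability` — chance that a single founder escapes
  the daily dilution bottlenecks and establishes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from . import cell as _cell
from ._engine import EstablishmentOutcome, TwoSpeciesModel, run_establishment_trials
from .cell import (
    CellState,
    FitnessModel,
    PlasmidSpecies,
    as_rng,
    cell_fitness,
    is_viable,
)
from .errors import (
    ExtinctionError,
    InvalidStateError,
    NoEquilibriumError,
    UndefinedResultError,
)

log = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "PopulationEnsemble",
    "FitnessTrajectory",
    "TuningResult",
    "advance_generation",
    "dilute",
    "realized_fitness",
    "tune_background_fitness",
    "equilibrium_composition",
    "phenotypic_delay_trajectories",
    "crossover_generation",
    "establishment_probability",
]


@dataclass
class SimulationConfig:
    """Parameters for one serial-dilution competition protocol.

    ``dilution_factor`` is the fold dilution applied every
    ``generations_per_cycle`` background doublings (1 for per-generation
    dilution regimes, ~log2(2000) for daily 1:2000 cycles).
    """

    dilution_factor: float = 2.0
    generations_per_cycle: int = 1
    n_generations: int = 500
    background_fitness: float = 1.0
    selection_on: bool = True
    establishment_multiple: float = 20.0
    division_substeps: int = 8
    division_rule: str = "doubling"  # or "linear": q = clamp(w/w_b) at S=1
    replication_scheme: str = "copy_once"
    fitness_model: FitnessModel = field(default_factory=FitnessModel)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.dilution_factor < 1.0:
            raise InvalidStateError("dilution_factor must be >= 1")

    @property
    def establishment_threshold(self) -> float:
        return self.establishment_multiple * self.dilution_factor


@dataclass
class PopulationEnsemble:
    """Focal cells aggregated by identical CellState (state -> multiplicity)."""

    cells: Dict[CellState, int] = field(default_factory=dict)

    @classmethod
    def from_cells(cls, states: Iterable[Tuple[CellState, int]]) -> "PopulationEnsemble":
        agg: Dict[CellState, int] = {}
        for state, m in states:
            if m < 0:
                raise InvalidStateError("cell multiplicities must be >= 0")
            if m:
                agg[state] = agg.get(state, 0) + int(m)
        return cls(agg)

    @property
    def n_cells(self) -> int:
        return sum(self.cells.values())

    def species(self) -> Tuple[PlasmidSpecies, ...]:
        seen: Dict[str, PlasmidSpecies] = {}
        for state in self.cells:
            for sp, _ in state.counts:
                seen.setdefault(sp.name, sp)
        return tuple(seen.values())


@dataclass
class FitnessTrajectory:
    """Across-replicate mean realized fitness per generation with 95% CI."""

    generations: np.ndarray
    mean: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_replicates: int

    def __len__(self) -> int:
        return len(self.generations)


@dataclass
class TuningResult:
    """Outcome of the background-fitness equilibrium search."""

    background_fitness: float
    mean_log_drift: float
    replicate_log_drifts: np.ndarray
    n_iterations: int
    bracket: Tuple[float, float]


# ----------------------------------------------------------------------
# Reference (generic, per-cell-state) generation operators
# ----------------------------------------------------------------------

def _growth_target(w: float, cfg: SimulationConfig) -> float:
    """Expected per-generation growth factor of a cell lineage."""
    r = w / cfg.background_fitness
    if cfg.division_rule == "doubling":
        return 2.0 ** r
    if cfg.division_rule == "linear":
        return 1.0 + min(max(r, 0.0), 1.0)
    raise InvalidStateError(f"unknown division rule {cfg.division_rule!r}")


def advance_generation(
    pop: PopulationEnsemble,
    cfg: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> PopulationEnsemble:
    """One background doubling of a focal ensemble (reference implementation).

    Viable cells divide stochastically so that a lineage of fitness w grows
    by ``2**(w/w_b)`` per generation in expectation; dividing cells double
    their plasmid pool and assort it evenly at random; daughters failing
    viability are removed.  Cells without autonomous plasmids never divide.
    An empty population is returned unchanged (extinction).
    """
    if cfg.background_fitness <= 0:
        raise InvalidStateError("background_fitness must be > 0")
    rng = as_rng(rng)
    current = {
        s: m for s, m in pop.cells.items() if m > 0 and is_viable(s, cfg.selection_on)
    }
    substeps = max(
        cfg.division_substeps,
        max(
            (int(math.ceil(math.log2(_growth_target(cell_fitness(s, cfg.fitness_model), cfg))))
             for s in current),
            default=1,
        ) or 1,
    )
    for _ in range(substeps):
        nxt: Dict[CellState, int] = {}
        for state, m in current.items():
            w = cell_fitness(state, cfg.fitness_model)
            can_divide = state.has_autonomous()
            g = _growth_target(w, cfg) if can_divide else 1.0
            q = min(max(g ** (1.0 / substeps) - 1.0, 0.0), 1.0)
            n_div = int(rng.binomial(m, q)) if q > 0 else 0
            if m - n_div:
                nxt[state] = nxt.get(state, 0) + (m - n_div)
            for _i in range(n_div):
                doubled = _cell.replicate_plasmids(state, rng, cfg.replication_scheme)
                for daughter in _cell.segregate(doubled, rng):
                    if is_viable(daughter, cfg.selection_on):
                        nxt[daughter] = nxt.get(daughter, 0) + 1
        current = nxt
    return PopulationEnsemble(current)


def dilute(
    pop: PopulationEnsemble,
    factor: float,
    rng: np.random.Generator | int | None = None,
) -> PopulationEnsemble:
    """Serial transfer: each cell survives independently with prob 1/factor."""
    if factor < 1.0:
        raise InvalidStateError("dilution factor must be >= 1")
    if factor == 1.0:
        return PopulationEnsemble(dict(pop.cells))
    rng = as_rng(rng)
    out = {}
    for state, m in pop.cells.items():
        k = int(rng.binomial(m, 1.0 / factor))
        if k:
            out[state] = k
    return PopulationEnsemble(out)


def realized_fitness(
    focal_sizes: Sequence[float],
    dilutions: Sequence[float],
    n_generations: float,
) -> float:
    """Fitness from doublings achieved relative to the background.

    ``log2(N_t * prod(dilution factors) / N_0) / n_generations`` — the number
    of doublings of the focal population (undoing the transfers) per
    background doubling.
    """
    n0, nt = float(focal_sizes[0]), float(focal_sizes[-1])
    if n0 <= 0 or nt <= 0:
        raise UndefinedResultError("realized fitness needs positive sizes at both ends")
    if n_generations <= 0:
        raise UndefinedResultError("n_generations must be positive")
    total_dilution = float(np.prod(np.asarray(dilutions, dtype=float)))
    return math.log2(nt * total_dilution / n0) / n_generations


# ----------------------------------------------------------------------
# Engine construction from cell states
# ----------------------------------------------------------------------

def _engine_model(
    initial_cell: CellState, cfg: SimulationConfig
) -> Tuple[TwoSpeciesModel, int]:
    """Map a (<= 2 species) cell onto the aggregated engine.

    Returns the model and the initial ancestral-slot count ``a``.  The
    "ancestral slot" is the autonomous, marker-bearing species; the other
    species (if any) is the mutant.
    """
    present = [(sp, n) for sp, n in initial_cell.counts if n > 0]
    if not 1 <= len(present) <= 2:
        raise InvalidStateError(
            "the aggregated simulator supports cells with 1 or 2 plasmid species"
        )
    fm = cfg.fitness_model
    anchors = [it for it in present if it[0].autonomous and it[0].carries_marker]
    if not anchors:
        raise InvalidStateError(
            "no autonomous marker-bearing species: the focal type cannot persist"
        )
    anchor, a0 = anchors[0]
    others = [it for it in present if it[0] is not anchor]
    if others:
        mutant, _ = others[0]
        lethal = cfg.selection_on and not mutant.carries_marker
        if not mutant.carries_marker and not mutant.autonomous:
            lethal = lethal or False
        cost_mut = fm.cost_of(mutant)
    else:
        lethal = False
        cost_mut = 0.0
    model = TwoSpeciesModel(
        cost_ancestral=fm.cost_of(anchor),
        cost_mutant=cost_mut,
        mutant_lethal_without_ancestral=bool(others) and lethal,
        copy_number=initial_cell.total,
        scheme=cfg.replication_scheme,
        fitness_floor=fm.floor,
    )
    return model, a0


# ----------------------------------------------------------------------
# Protocol 1: background-fitness tuning and equilibrium composition
# ----------------------------------------------------------------------

def _burn_in_hold(
    model: TwoSpeciesModel,
    states: np.ndarray,
    background_fitness: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    n_cells: int,
    n_generations: int,
) -> np.ndarray:
    """Let the within-cell composition equilibrate at a held population size.

    Each generation grows and transfers normally, then the population is
    resampled (multinomially over cell states) back to ``n_cells``.
    """
    for _ in range(n_generations):
        states = model.advance(states, background_fitness, rng, cfg.division_substeps)
        totals = states.sum(axis=1)
        if (totals == 0).any():
            raise ExtinctionError("population extinct during burn-in")
        p = states / totals[:, None]
        states = rng.multinomial(n_cells, p)
    return states.astype(np.int64)


def tune_background_fitness(
    initial_cell: CellState,
    cfg: SimulationConfig,
    rng: np.random.Generator | int | None = None,
    n_cells: int = 10_000,
    n_replicates: int = 10,
    tolerance: float = 0.005,
    bracket: Tuple[float, float] = (0.25, 1.2),
    burn_in_generations: int = 100,
) -> TuningResult:
    """Bisect on background fitness until the focal population is stable.

    A population seeded with ``n_cells`` copies of ``initial_cell`` is run
    for ``cfg.n_generations`` generations of growth with
    ``cfg.dilution_factor``-fold serial dilutions; stability means the mean
    log size change across replicates is near zero.  The tuned background
    fitness is, by construction, the realized equilibrium fitness of the
    focal type.

    A population founded by single-mutant cells is far from its within-cell
    compositional equilibrium, so its early growth does not reflect the
    equilibrium fitness (that early deficit is the phenotypic delay).  During
    the first ``burn_in_generations`` the population is therefore held at its
    working size (resampled to ``n_cells`` after each transfer) while the
    composition equilibrates; drift is measured over the remaining
    generations of free growth.
    """
    rng = as_rng(rng if rng is not None else cfg.seed)
    model, a0 = _engine_model(initial_cell, cfg)
    burn_in_generations = min(burn_in_generations, cfg.n_generations // 2)

    def drift(wb: float) -> Tuple[float, np.ndarray]:
        states = np.zeros((n_replicates, model.copy_number + 1), dtype=np.int64)
        states[:, a0] = n_cells
        states = _burn_in_hold(
            model, states, wb, cfg, rng, n_cells, burn_in_generations
        )
        _, sizes = model.run_growth(
            states,
            cfg.n_generations - burn_in_generations,
            wb,
            cfg.dilution_factor,
            rng,
            cfg.division_substeps,
            stop_above=100.0 * n_cells,
            stop_below=n_cells / 100.0,
        )
        final = np.maximum(sizes[:, -1], 0.25)
        drifts = np.log(final / n_cells)
        return float(drifts.mean()), drifts

    lo, hi = bracket
    d_lo, _ = drift(lo)
    d_hi, _ = drift(hi)
    if not (d_lo > 0 > d_hi):
        raise NoEquilibriumError(
            f"no demographic equilibrium in background-fitness bracket {bracket}: "
            f"drift({lo})={d_lo:.3g}, drift({hi})={d_hi:.3g}"
        )
    iterations = 0
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        d_mid, _ = drift(mid)
        if d_mid > 0:
            lo = mid
        else:
            hi = mid
        iterations += 1
        log.info(
            "bisection %d: w_b in [%.4f, %.4f], drift(%.4f)=%+.3f",
            iterations, lo, hi, mid, d_mid,
        )
    wb = 0.5 * (lo + hi)
    mean_drift, drifts = drift(wb)
    return TuningResult(
        background_fitness=wb,
        mean_log_drift=mean_drift,
        replicate_log_drifts=drifts,
        n_iterations=iterations,
        bracket=bracket,
    )


def equilibrium_composition(
    initial_cell: CellState,
    cfg: SimulationConfig,
    background_fitness: float,
    rng: np.random.Generator | int | None = None,
    n_cells: int = 10_000,
    burn_in_fraction: float = 0.5,
) -> Dict[str, float]:
    """Time-averaged mean per-cell copy number by species at equilibrium.

    Runs the serial-dilution protocol at the tuned background fitness with
    the population held at its working size (resampled to ``n_cells`` after
    each transfer, so the near-critical size performs no random walk) and
    averages the per-cell species counts over the post-burn-in generations.
    """
    rng = as_rng(rng if rng is not None else cfg.seed)
    model, a0 = _engine_model(initial_cell, cfg)
    n = model.copy_number
    states = np.zeros((1, n + 1), dtype=np.int64)
    states[0, a0] = n_cells
    burn_in = int(burn_in_fraction * cfg.n_generations)
    a_idx = np.arange(n + 1)
    means: List[float] = []
    for t in range(cfg.n_generations):
        states = model.advance(states, background_fitness, rng, cfg.division_substeps)
        total = states.sum()
        if total == 0:
            raise ExtinctionError(
                "population extinct during equilibrium measurement", trajectory=means
            )
        if t >= burn_in:
            means.append(float((states[0] * a_idx).sum() / total))
        states = rng.multinomial(n_cells, states[0] / total)[None, :].astype(np.int64)
    mean_anchor = float(np.mean(means))
    present = [(sp, m) for sp, m in initial_cell.counts if m > 0]
    anchor = next(sp for sp, _ in present if sp.autonomous and sp.carries_marker)
    out = {anchor.name: mean_anchor}
    for sp, _ in present:
        if sp is not anchor:
            out[sp.name] = n - mean_anchor
    return out


# ----------------------------------------------------------------------
# Protocol 2: phenotypic delay
# ----------------------------------------------------------------------

def phenotypic_delay_trajectories(
    mutant_species: PlasmidSpecies,
    cfg: SimulationConfig,
    rng: np.random.Generator | int | None = None,
    n_replicates: int = 200,
    n_cells: int = 20_000,
    n_generations: int = 50,
    ancestral: PlasmidSpecies = _cell.ANCESTRAL,
    copy_number: int = _cell.DEFAULT_COPY_NUMBER,
) -> FitnessTrajectory:
    """Realized-fitness trajectories of populations of new-mutant carriers.

    Each replicate starts with ``n_cells`` cells carrying 1 copy of the
    mutant plasmid and ``copy_number - 1`` ancestral copies and is propagated
    with ``cfg.dilution_factor``-fold dilutions per generation against the
    ancestral-carrier background.  The per-generation realized fitness
    (doublings achieved relative to the background, times the background's
    own fitness so that values are on the common reference scale) is
    averaged across replicates with a normal-approximation 95% band.

    Per-generation realized fitness is a growth ratio, so it is unaffected
    by holding the population at its working size; after each growth
    measurement and transfer every replicate is resampled back to
    ``n_cells`` (mutant lineages outgrow the background roughly threefold
    per generation here, which would otherwise overflow any bookkeeping
    within the 50 simulated generations).
    """
    rng = as_rng(rng if rng is not None else cfg.seed)
    seed_cell = CellState.from_counts(
        {ancestral: copy_number - 1, mutant_species: 1}
    )
    model, a0 = _engine_model(seed_cell, cfg)
    wb = cfg.background_fitness
    states = np.zeros((n_replicates, copy_number + 1), dtype=np.int64)
    states[:, a0] = n_cells
    prev = states.sum(axis=1).astype(float)
    w = np.full((n_replicates, n_generations), np.nan)
    for t in range(n_generations):
        states = model.advance(states, wb, rng, cfg.division_substeps)
        now = states.sum(axis=1).astype(float)
        alive = (now > 0) & (prev > 0)
        w[alive, t] = wb * np.log2(now[alive] / prev[alive])
        states = model.dilute(states, cfg.dilution_factor, rng)
        totals = states.sum(axis=1)
        ok = totals > 0
        if ok.any():
            resampled = rng.multinomial(
                n_cells, states[ok] / totals[ok, None]
            ).astype(np.int64)
            states[ok] = resampled
        prev = np.where(ok, float(n_cells), 0.0)
    alive_reps = ~np.isnan(w).any(axis=1)
    if not alive_reps.any():
        raise ExtinctionError("all replicates went extinct")
    w = w[alive_reps]
    mean = w.mean(axis=0)
    se = w.std(axis=0, ddof=1) / math.sqrt(w.shape[0])
    return FitnessTrajectory(
        generations=np.arange(1, n_generations + 1),
        mean=mean,
        ci_lower=mean - 1.959964 * se,
        ci_upper=mean + 1.959964 * se,
        n_replicates=int(alive_reps.sum()),
    )


def crossover_generation(
    sat: FitnessTrajectory, dele: FitnessTrajectory
) -> int:
    """Largest g such that the satellite mean exceeds the deletion mean for
    every generation t <= g; 0 if the satellite is never above at t = 1."""
    if len(sat) != len(dele):
        raise InvalidStateError("trajectories must have equal length")
    g = 0
    for t in range(len(sat)):
        if sat.mean[t] > dele.mean[t]:
            g = t + 1
        else:
            break
    return g


# ----------------------------------------------------------------------
# Protocol 3: establishment probability
# ----------------------------------------------------------------------

def establishment_probability(
    mutant_species: PlasmidSpecies,
    cfg: SimulationConfig,
    n_trials: int,
    rng: np.random.Generator | int | None = None,
    ancestral: PlasmidSpecies = _cell.ANCESTRAL,
    copy_number: int = _cell.DEFAULT_COPY_NUMBER,
) -> EstablishmentOutcome:
    """Chance that a single new-mutant cell escapes the dilution bottlenecks.

    Each trial seeds one cell with 1 mutant + (copy_number - 1) ancestral
    plasmid copies at a cell division sampled proportional to the number of
    divisions per generation within a growth cycle, and follows its
    descendants through ``cfg.dilution_factor``-fold transfers every
    ``cfg.generations_per_cycle`` generations until extinction or until the
    lineage reaches ``cfg.establishment_threshold`` cells at a cycle end.
    """
    if n_trials < 1:
        raise InvalidStateError("n_trials must be >= 1")
    rng = as_rng(rng if rng is not None else cfg.seed)
    seed_cell = CellState.from_counts(
        {ancestral: copy_number - 1, mutant_species: 1}
    )
    model, a0 = _engine_model(seed_cell, cfg)
    return run_establishment_trials(
        model,
        n_trials,
        cfg.background_fitness,
        rng,
        dilution_factor=cfg.dilution_factor,
        generations_per_cycle=cfg.generations_per_cycle,
        establishment_multiple=cfg.establishment_multiple,
        substeps=cfg.division_substeps,
        founder_state=a0,
    )
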