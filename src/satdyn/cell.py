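"""Within-cell layer: plasmid species, cell fitness, replication, segregation.

A cell is a multiset of plasmid copies drawn from a small number of species
(full-length ancestral plasmid, nonautonomous satellite, accessory-gene
deletion plasmid).  The nominal copy number is fixed (18 by default for the
IncQ plasmid studied here): at division the pool is exactly doubled and then
randomly but evenly assorted to the two daughters, i.e. each daughter draws
half the doubled pool uniformly without replacement (multivariate
hypergeometric).

Replication schemes
-------------------
``copy_once`` (default)
    Every plasmid is copied exactly once: the pool is doubled
    deterministically.  All species have equal replication chances by
    construction, consistent with initiation being rate-limiting.
``polya``
    The doubling is achieved by n sequential template draws (n = starting
    total), each template chosen uniformly from the *current* pool including
    copies made earlier in the same round (urn with replacement).  Species
    fractions are a martingale, but composition acquires extra variance.
``frozen``
    n template draws from the *starting* pool (multinomial); intermediate
    variance between the two schemes above.

Replication of any plasmid requires at least one autonomous plasmid in the
cell: Rep proteins act in trans, so a single autonomous copy licenses
replication of every plasmid present, satellites included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np

from .errors import InvalidCallError, InvalidStateError, ReplicationImpossibleError

__all__ = [
    "PlasmidSpecies",
    "CellState",
    "FitnessModel",
    "cell_fitness",
    "replicate_plasmids",
    "segregate",
    "is_viable",
    "as_rng",
    "REPLICATION_SCHEMES",
]

REPLICATION_SCHEMES = ("copy_once", "polya", "frozen")


def as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    """Coerce a seed or Generator into a numpy Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class PlasmidSpecies:
    """One plasmid class (ancestral, satellite, or accessory-gene deletion).

    Parameters
    ----------
    name : str
        Unique identifier within a model.
    autonomous : bool
        Whether the species encodes a complete replication machinery.
    carries_marker : bool
        Whether the species carries the selected resistance marker.
    per_copy_cost : float
        Additive fitness cost per plasmid copy, a fraction in [0, 1].
    """

    name: str
    autonomous: bool
    carries_marker: bool
    per_copy_cost: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_copy_cost <= 1.0:
            raise InvalidStateError(
                f"per_copy_cost must lie in [0, 1], got {self.per_copy_cost!r}"
            )


# The study's plasmid species: costs of 3.06% per full-length copy and 0.50%
# per deletion-plasmid copy reproduce the measured fitness of pure carriers;
# satellites are cost-free.
ANCESTRAL = PlasmidSpecies("ancestral", autonomous=True, carries_marker=True,
                           per_copy_cost=0.0306)
SATELLITE = PlasmidSpecies("satellite", autonomous=False, carries_marker=False,
                           per_copy_cost=0.0)
DELETION = PlasmidSpecies("deletion", autonomous=True, carries_marker=True,
                          per_copy_cost=0.0050)

#: Nominal total copy number per newborn cell.
DEFAULT_COPY_NUMBER = 18


@dataclass(frozen=True)
class CellState:
    """Immutable multiset of plasmid counts per species in one cell."""

    counts: Tuple[Tuple[PlasmidSpecies, int], ...]

    @classmethod
    def from_counts(cls, counts: Mapping[PlasmidSpecies, int]) -> "CellState":
        items = tuple(sorted(((sp, int(n)) for sp, n in counts.items()),
                             key=lambda it: it[0].name))
        state = cls(items)
        state.validate()
        return state

    def validate(self) -> None:
        seen = set()
        for sp, n in self.counts:
            if n < 0:
                raise InvalidStateError(f"negative count {n} for {sp.name}")
            if sp.name in seen:
                raise InvalidStateError(f"duplicate species name {sp.name!r}")
            seen.add(sp.name)

    @property
    def total(self) -> int:
        return sum(n for _, n in self.counts)

    def count_of(self, species: PlasmidSpecies) -> int:
        for sp, n in self.counts:
            if sp == species:
                return n
        return 0

    def species(self) -> Tuple[PlasmidSpecies, ...]:
        return tuple(sp for sp, _ in self.counts)

    def as_dict(self) -> Dict[PlasmidSpecies, int]:
        return dict(self.counts)

    def has_autonomous(self) -> bool:
        return any(sp.autonomous and n > 0 for sp, n in self.counts)

    def has_marker(self) -> bool:
        return any(sp.carries_marker and n > 0 for sp, n in self.counts)

    def __repr__(self) -> str:  # compact, e.g. CellState(ancestral=5, satellite=13)
        inner = ", ".join(f"{sp.name}={n}" for sp, n in self.counts)
        return f"CellState({inner})"


@dataclass(frozen=True)
class FitnessModel:
    """Additive per-copy fitness model: w = max(floor, baseline - sum n_s c_s)."""

    baseline: float = 1.0
    floor: float = 0.0
    #: Optional cost overrides by species; defaults to each species' own cost.
    costs: Tuple[Tuple[PlasmidSpecies, float], ...] = field(default_factory=tuple)

    def cost_of(self, species: PlasmidSpecies) -> float:
        for sp, c in self.costs:
            if sp == species:
                return c
        return species.per_copy_cost


def cell_fitness(cell: CellState, model: FitnessModel | None = None) -> float:
    """Relative fitness of a cell under the additive per-copy cost model.

    Returns ``max(floor, baseline - sum_s counts[s] * cost[s])``.
    """
    model = model or FitnessModel()
    cell.validate()
    burden = sum(n * model.cost_of(sp) for sp, n in cell.counts)
    return max(model.floor, model.baseline - burden)


def replicate_plasmids(
    cell: CellState,
    rng: np.random.Generator | int | None = None,
    scheme: str = "copy_once",
) -> CellState:
    """Exactly double the plasmid pool of a cell.

    Raises
    ------
    ReplicationImpossibleError
        If the cell holds no autonomous plasmid (no replication machinery);
        the cell is left unchanged and the caller decides its fate.
    """
    cell.validate()
    if not cell.has_autonomous():
        raise ReplicationImpossibleError(
            f"no autonomous plasmid in {cell!r}; replication impossible"
        )
    if scheme not in REPLICATION_SCHEMES:
        raise ValueError(f"unknown replication scheme {scheme!r}")
    species = [sp for sp, _ in cell.counts]
    start = np.array([n for _, n in cell.counts], dtype=np.int64)
    n = int(start.sum())
    if scheme == "copy_once":
        final = 2 * start
    elif scheme == "frozen":
        rng = as_rng(rng)
        new = rng.multinomial(n, start / n)
        final = start + new
    else:  # polya: sequential draws from the growing pool
        rng = as_rng(rng)
        pool = start.astype(float).copy()
        for _ in range(n):
            p = pool / pool.sum()
            i = rng.choice(len(pool), p=p)
            pool[i] += 1
        final = pool.astype(np.int64)
    return CellState.from_counts(dict(zip(species, final.tolist())))


def segregate(
    cell: CellState, rng: np.random.Generator | int | None = None
) -> Tuple[CellState, CellState]:
    """Randomly but evenly assort a doubled pool to two daughter cells.

    Daughter 1 receives exactly half the pool drawn uniformly without
    replacement (multivariate hypergeometric); daughter 2 the complement.
    """
    cell.validate()
    total = cell.total
    if total % 2 != 0:
        raise InvalidCallError(
            f"cannot evenly assort an odd pool of {total}; replicate first"
        )
    rng = as_rng(rng)
    species = [sp for sp, _ in cell.counts]
    pool = np.array([n for _, n in cell.counts], dtype=np.int64)
    d1 = rng.multivariate_hypergeometric(pool, total // 2)
    d2 = pool - d1
    return (
        CellState.from_counts(dict(zip(species, d1.tolist()))),
        CellState.from_counts(dict(zip(species, d2.tolist()))),
    )


def is_viable(cell: CellState, selection_on: bool) -> bool:
    """Whether a cell survives: under selection it needs >= 1 marker copy."""
    cell.validate()
    if not selection_on:
        return True
    return cell.has_marker()


def make_cell(
    n_ancestral: int = 0,
    n_satellite: int = 0,
    n_deletion: int = 0,
) -> CellState:
    """Convenience constructor using the bundled study species."""
    counts: Dict[PlasmidSpecies, int] = {}
    if n_ancestral:
        counts[ANCESTRAL] = n_ancestral
    if n_satellite:
        counts[SATELLITE] = n_satellite
    if n_deletion:
        counts[DELETION] = n_deletion
    if not counts:
        counts[ANCESTRAL] = 0
    return CellState.from_counts(counts)
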