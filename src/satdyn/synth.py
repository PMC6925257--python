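"""Synthetic fixtures: random circular plasmids with planted near-repeats,
miniature annotated plasmid maps, and the bundled study presets.

Everything here is a pure function of its seed, so every downstream stage
(repeat scanning, deletion-space counting, simulation protocols) is testable
without any downloaded data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from . import intervals as iv
from .cell import ANCESTRAL, DELETION, SATELLITE, as_rng
from .delspace import Feature, PlasmidMap
from .errors import LayoutError
from .population import SimulationConfig
from .repeats import RepeatMatch

__all__ = [
    "SyntheticSpec",
    "random_plasmid_sequence",
    "plant_repeat_pair",
    "make_toy_plasmid_map",
    "study_presets",
    "ancestral_carrier_fitness",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic fixture."""

    length: int = 2000
    gc_fraction: float = 0.5
    #: (alignment_length, pos_a, pos_b, n_mismatches, n_indels) per plant
    repeats: Tuple[Tuple[int, int, int, int, int], ...] = ()
    seed: Optional[int] = None


def random_plasmid_sequence(
    length: int,
    gc_fraction: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> str:
    """I.i.d. circular nucleotide sequence at the requested GC content."""
    if length <= 0:
        raise LayoutError("sequence length must be positive")
    if not 0.0 <= gc_fraction <= 1.0:
        raise LayoutError("GC fraction must be in [0, 1]")
    rng = as_rng(rng)
    at, gc = (1 - gc_fraction) / 2, gc_fraction / 2
    idx = rng.choice(4, size=length, p=[at, gc, gc, at])
    return _BASES[idx].tobytes().decode()


def _spread_interior(n_cols: int, k: int) -> List[int]:
    """k interior column indices (1..n_cols-2) spread as evenly as possible."""
    if k == 0:
        return []
    usable = n_cols - 2
    if k > usable:
        raise LayoutError(f"cannot place {k} mismatches inside {n_cols} columns")
    return [1 + round(i * (usable - 1) / max(k - 1, 1)) for i in range(k)]


def plant_repeat_pair(
    sequence: str,
    length: int,
    pos_a: int,
    pos_b: int,
    n_mismatches: int = 0,
    n_indels: int = 0,
    rng: np.random.Generator | int | None = None,
) -> Tuple[str, RepeatMatch]:
    """Overwrite two loci so they align with the requested length/mismatches.

    ``length`` counts alignment columns; with one indel the locus at
    ``pos_b`` carries the extra base.  Substituted and indel columns are
    interior (the alignment must begin and end on matches) and spread
    evenly.  Returns the edited sequence and the planted ground truth.
    """
    rng = as_rng(rng)
    L = len(sequence)
    if n_indels > min(1, n_mismatches):
        raise LayoutError("n_indels must be <= min(1, n_mismatches)")
    if length < max(2, n_mismatches + 2):
        raise LayoutError("length too short for the requested mismatches")
    len_b = length
    len_a = length - n_indels
    if max(len_a, len_b) >= L:
        raise LayoutError("planted locus does not fit on the circle")
    locus_a = iv.normalize(pos_a, len_a, L)
    locus_b = iv.normalize(pos_b, len_b, L)
    if iv.overlaps(locus_a, locus_b, L):
        raise LayoutError("planted loci overlap")

    core = rng.choice(4, size=length)
    cols = _spread_interior(length, n_mismatches)
    indel_cols = set(cols[: n_indels])
    sub_cols = [c for c in cols if c not in indel_cols]
    b_bases = _BASES[core]
    a_list = []
    for c in range(length):
        if c in indel_cols:
            continue  # base exists only in locus_b
        if c in sub_cols:
            a_list.append(_BASES[(core[c] + 1 + rng.integers(3)) % 4])
        else:
            a_list.append(b_bases[c])
    a_seq = bytes(a_list).decode()
    b_seq = b_bases.tobytes().decode()

    out = list(sequence)
    for locus, text in ((locus_a, a_seq), (locus_b, b_seq)):
        for k, ch in enumerate(text):
            out[(locus[0] + k) % L] = ch
    truth = RepeatMatch(
        *((locus_a, locus_b) if locus_a <= locus_b else (locus_b, locus_a)),
        alignment_length=length,
        n_mismatches=n_mismatches,
        n_indels=n_indels,
    )
    return "".join(out), truth


def make_toy_plasmid_map(
    length: int = 2000,
    n_rep_genes: int = 3,
    n_accessory: int = 2,
) -> PlasmidMap:
    """Miniature annotated plasmid in the study plasmid's feature order:
    origin, replication genes, marker, accessory genes, back to the origin."""
    if n_rep_genes < 1 or n_accessory < 1:
        raise LayoutError("need at least one rep gene and one accessory gene")
    # proportional layout with intergenic gaps
    blocks: List[Tuple[str, str, float]] = [("oriV", "origin", 0.05)]
    for i in range(n_rep_genes):
        blocks.append((f"rep{chr(ord('A') + i)}", "rep_gene", 0.12))
    blocks.append(("aadA", "marker", 0.12))
    for i in range(n_accessory):
        blocks.append((("lacI", "gfp")[i % 2] + ("" if i < 2 else str(i)),
                       "accessory", 0.10))
    gap = 0.02
    total = sum(w for _, _, w in blocks) + gap * len(blocks)
    feats = []
    pos = 0
    for name, role, w in blocks:
        span = max(4, int(w / total * length))
        if pos + span >= length:
            raise LayoutError("features do not fit on the requested circle")
        feats.append(Feature(name, role, (pos, span)))
        pos += span + max(2, int(gap / total * length))
    pmap = PlasmidMap(length, tuple(feats))
    pmap.require_roles()
    for i, f in enumerate(feats):
        for g in feats[i + 1 :]:
            if iv.overlaps(f.interval, g.interval, length):
                raise LayoutError(f"features {f.name} and {g.name} overlap")
    return pmap


def ancestral_carrier_fitness(copy_number: int = 18, cost: float = 0.0306) -> float:
    """Model fitness of a cell carrying only full-length plasmid copies."""
    return 1.0 - copy_number * cost


def _load_presets() -> dict:
    with resources.files("satdyn.data").joinpath("presets.yaml").open() as fh:
        return yaml.safe_load(fh)


def study_presets(desk: bool = False) -> Dict[str, dict]:
    """The three study protocols exactly as published, plus the cost model.

    With ``desk=True`` the documented scaled-down variants (fewer cells,
    replicates, trials) are substituted; each desk preset is flagged with
    ``scaled_down: True``.

    Returns a dict with keys "species", "copy_number", "equilibrium",
    "delay", "establishment"; each protocol entry carries a ready
    :class:`SimulationConfig` under "config" plus its protocol sizes.
    """
    raw = _load_presets()
    costs = raw["fitness"]["costs"]
    copy_number = raw["fitness"]["copy_number"]
    wb_ancestral = 1.0 - copy_number * costs["ancestral"]
    out: Dict[str, dict] = {
        "species": {
            "ancestral": ANCESTRAL,
            "satellite": SATELLITE,
            "deletion": DELETION,
        },
        "copy_number": copy_number,
        "repeat_params": dict(raw["repeat_params"]),
    }
    protos = {k: dict(v) for k, v in raw["protocols"].items()}
    if desk:
        for name, override in raw["desk"].items():
            protos[name].update(override)
    eq = protos["equilibrium"]
    out["equilibrium"] = {
        "config": SimulationConfig(
            dilution_factor=eq["dilution_factor"],
            n_generations=eq["n_generations"],
            selection_on=eq.get("selection_on", True),
        ),
        "n_cells": eq["n_cells"],
        "n_replicates": eq["n_replicates"],
        "scaled_down": desk,
    }
    dl = protos["delay"]
    out["delay"] = {
        "config": SimulationConfig(
            dilution_factor=dl["dilution_factor"],
            n_generations=dl["n_generations"],
            background_fitness=wb_ancestral,
        ),
        "n_cells": dl["n_cells"],
        "n_replicates": dl["n_replicates"],
        "scaled_down": desk,
    }
    es = protos["establishment"]
    out["establishment"] = {
        "config": SimulationConfig(
            dilution_factor=es["dilution_factor"],
            generations_per_cycle=es["generations_per_cycle"],
            establishment_multiple=es["establishment_multiple"],
            background_fitness=wb_ancestral,
        ),
        "n_trials": es["n_trials"],
        "scaled_down": desk,
    }
    return out
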