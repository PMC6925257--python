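"""Readers/writers for annotated plasmid maps, repeat tables, region files,
and the competition-assay fitness calculation.

All coordinates in all satdyn inputs and outputs are 0-based half-open on
the circle; GenBank's 1-based inclusive convention is translated at this
boundary (Biopython already exposes 0-based half-open locations).  Strand is
ignored: deletion arithmetic and direct-repeat logic operate on the forward
strand of the circle.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import SeqIO

from . import __version__
from .delspace import ROLES, Feature, PlasmidMap
from .errors import InputFormatError, UndefinedResultError
from .repeats import RepeatMatch

__all__ = [
    "read_plasmid_map",
    "read_map_tsv",
    "write_map_tsv",
    "write_repeats_tsv",
    "read_regions_bed",
    "write_regions_bed",
    "fitness_from_counts",
    "RunManifest",
]

#: Default feature-name -> role mapping for the study plasmid's annotation.
DEFAULT_ROLE_MAPPING: Dict[str, str] = {
    "oriv": "origin",
    "repa": "rep_gene",
    "repb": "rep_gene",
    "repc": "rep_gene",
    "aada": "marker",
    "gfp": "accessory",
    "laci": "accessory",
}

_FEATURE_TYPES = {"CDS", "gene", "rep_origin", "misc_feature", "oriT"}


def _feature_name(feat) -> Optional[str]:
    for key in ("gene", "label", "locus_tag", "product", "note"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return None


def read_plasmid_map(
    path: str | Path,
    role_mapping: Optional[Dict[str, str]] = None,
    strict: bool = False,
) -> Tuple[PlasmidMap, str]:
    """Read a single circular GenBank record (or the map TSV dialect).

    GenBank features are converted to 0-based half-open circular intervals;
    an origin-spanning two-part join becomes one wrapped interval.  Feature
    names are assigned roles through ``role_mapping`` (case-insensitive;
    defaults cover the study plasmid's gene names).  Unmapped features get
    role "other", or raise when ``strict``.

    Returns (PlasmidMap, sequence); the TSV dialect carries no sequence and
    returns an empty string.
    """
    path = Path(path)
    if path.suffix.lower() in {".tsv", ".txt"}:
        return read_map_tsv(path), ""
    mapping = {k.lower(): v for k, v in (role_mapping or DEFAULT_ROLE_MAPPING).items()}
    records = list(SeqIO.parse(str(path), "genbank"))
    if len(records) != 1:
        raise InputFormatError(
            f"{path} holds {len(records)} records; a single circular record is required"
        )
    rec = records[0]
    L = len(rec.seq)
    feats: List[Feature] = []
    for f in rec.features:
        if f.type not in _FEATURE_TYPES:
            continue
        name = _feature_name(f)
        if name is None:
            continue
        role = mapping.get(name.lower())
        if role is None:
            if strict:
                raise InputFormatError(f"no role mapping for feature {name!r}")
            role = "other"
        parts = f.location.parts
        if len(parts) == 1:
            start, end = int(parts[0].start), int(parts[0].end)
            interval = (start % L, end - start)
        elif len(parts) == 2 and int(parts[0].end) == L and int(parts[1].start) == 0:
            start = int(parts[0].start)
            interval = (start, (L - start) + int(parts[1].end))
        else:
            raise InputFormatError(
                f"unsupported compound location for feature {name!r}"
            )
        feats.append(Feature(name, role, interval))
    if not feats:
        raise InputFormatError(f"no usable features found in {path}")
    return PlasmidMap(L, tuple(feats)), str(rec.seq)


def read_map_tsv(path: str | Path) -> PlasmidMap:
    """Plain map dialect: header '#length=<L>', rows name/role/start/end."""
    length = None
    feats: List[Feature] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("#length="):
                length = int(line.split("=", 1)[1])
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise InputFormatError(f"bad map line: {line!r}")
        name, role, start, end = parts[0], parts[1], int(parts[2]), int(parts[3])
        if role not in ROLES:
            raise InputFormatError(f"unknown role {role!r} in {path}")
        if length is None:
            raise InputFormatError("map TSV must declare '#length=' before features")
        span = end - start if end > start else length - start + end
        feats.append(Feature(name, role, (start % length, span)))
    if length is None or not feats:
        raise InputFormatError(f"no features found in {path}")
    return PlasmidMap(length, tuple(feats))


def write_map_tsv(pmap: PlasmidMap, path: str | Path) -> None:
    lines = [f"#length={pmap.length}", "#name\trole\tstart\tend"]
    for f in pmap.features:
        start, span = f.interval
        end = (start + span) % pmap.length
        lines.append(f"{f.name}\t{f.role}\t{start}\t{end}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_repeats_tsv(
    matches: Sequence[RepeatMatch], circle: int, path: str | Path,
    header_comment: str = "",
) -> None:
    """Repeat table: 0-based half-open circular coordinates per locus."""
    lines = []
    if header_comment:
        lines.extend("# " + l for l in header_comment.splitlines())
    lines.append(
        "locus_a_start\tlocus_a_end\tlocus_b_start\tlocus_b_end\t"
        "length\tmismatches\tindels\tidentity"
    )
    for m in matches:
        a0, al = m.locus_a
        b0, bl = m.locus_b
        lines.append(
            f"{a0}\t{(a0 + al) % circle}\t{b0}\t{(b0 + bl) % circle}\t"
            f"{m.alignment_length}\t{m.n_mismatches}\t{m.n_indels}\t"
            f"{m.identity:.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_regions_bed(path: str | Path, circle: int) -> List[Tuple[int, int]]:
    """BED-like circular intervals: chrom/start/end (end < start wraps)."""
    out: List[Tuple[int, int]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise InputFormatError(f"bad region line: {line!r}")
        start, end = int(parts[1]), int(parts[2])
        span = end - start if end > start else circle - start + end
        out.append((start % circle, span))
    if not out:
        raise InputFormatError(f"no regions found in {path}")
    return out


def write_regions_bed(
    regions: Dict[str, Tuple[int, int]], circle: int, path: str | Path,
    chrom: str = "plasmid",
) -> None:
    lines = [f"# circular intervals on {chrom} (length {circle}); end < start wraps"]
    for name, (start, span) in regions.items():
        lines.append(f"{chrom}\t{start}\t{(start + span) % circle}\t{name}")
    Path(path).write_text("\n".join(lines) + "\n")


def fitness_from_counts(
    a0: float, af: float, b0: float, bf: float, total_dilution: float = 1.0
) -> float:
    """Relative fitness from a co-culture competition assay.

    Ratio of realized Malthusian parameters:
    ``ln(af * D / a0) / ln(bf * D / b0)`` where D is the total fold growth
    permitted by the dilution (both competitors share it, so any common
    plating/volume scaling cancels).
    """
    if min(a0, af, b0, bf) <= 0:
        raise UndefinedResultError("colony counts must all be positive")
    denom = math.log(bf * total_dilution / b0)
    if denom == 0:
        raise UndefinedResultError("reference strain did not grow; fitness undefined")
    return math.log(af * total_dilution / a0) / denom


@dataclass
class RunManifest:
    """Provenance record written once per CLI run; re-running with the same
    manifest reproduces stochastic outputs bit-for-bit."""

    command: str
    config: dict
    seed: Optional[int]
    outputs: List[str] = field(default_factory=list)
    version: str = __version__
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")
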