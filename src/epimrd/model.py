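"""Core domain types shared by all analysis stages.

The package works on two substrates:

* methylation-array style **beta matrices** (CpG x sample, values in [0, 1])
  with a control/AML group assignment, used for candidate-CpG selection and
  the array-based AML-score; and
* **bisulfite amplicon sequencing (BA-seq) read patterns** — each sequencing
  read reduced to the ordered binary methylation states of the CpGs in one
  amplicon region — used for read-level anomaly detection.

Genomic coordinates are 1-based, inclusive, on the reference (+) strand; a
CpG's position is the C of the CG dinucleotide (the convention of Illumina
array manifests, so positions line up with cg-identifiers).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "EpimrdError",
    "ValidationError",
    "PanelError",
    "HYPER",
    "HYPO",
    "AmpliconRegion",
    "RegionPanel",
    "BetaMatrix",
    "ReadPattern",
    "SampleReads",
    "AnomalyResult",
    "load_region_panel",
    "write_panel",
    "default_panel",
    "load_beta_matrix",
]


class EpimrdError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(EpimrdError):
    """Input violated a documented invariant."""


class PanelError(ValidationError):
    """Region-panel configuration is malformed or inconsistent."""


HYPER = "hyper_in_aml"
HYPO = "hypo_in_aml"
_DIRECTIONS = (HYPER, HYPO)


@dataclass(frozen=True)
class AmpliconRegion:
    """One BA-seq target region.

    ``cpg_positions`` are the C positions of the region's CpGs in strictly
    increasing genomic order; ``target_index`` points at the anchor CpG (the
    array probe the region was designed around).  ``direction`` states how the
    anchor behaves in AML relative to healthy blood: ``hyper_in_aml`` regions
    are unmethylated in controls and gain methylation in leukemia,
    ``hypo_in_aml`` the reverse.  ``snp_positions`` are optional positions of
    known intra-amplicon SNPs usable for allele splitting; each must be at
    least 3 bp from both bases of every CpG dinucleotide so that a genuine
    sequence variant cannot be confused with a bisulfite conversion event.
    """

    region_id: str
    anchor_cpg: str
    chrom: str
    cpg_positions: tuple[int, ...]
    target_index: int
    direction: str
    snp_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        pos = tuple(int(p) for p in self.cpg_positions)
        object.__setattr__(self, "cpg_positions", pos)
        object.__setattr__(self, "snp_positions", tuple(int(p) for p in self.snp_positions))
        if len(pos) == 0:
            raise PanelError(f"region {self.region_id!r}: no CpG positions")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise PanelError(
                f"region {self.region_id!r}: cpg_positions must be strictly increasing"
            )
        if not 0 <= self.target_index < len(pos):
            raise PanelError(
                f"region {self.region_id!r}: target_index {self.target_index} out of "
                f"range for {len(pos)} CpGs"
            )
        if self.direction not in _DIRECTIONS:
            raise PanelError(
                f"region {self.region_id!r}: direction must be one of {_DIRECTIONS}, "
                f"got {self.direction!r}"
            )
        for snp in self.snp_positions:
            for c_pos in pos:
                # distance to both the C and the G of the dinucleotide
                if min(abs(snp - c_pos), abs(snp - (c_pos + 1))) < 3:
                    raise PanelError(
                        f"region {self.region_id!r}: SNP position {snp} is closer "
                        f"than 3 bp to the CpG at {c_pos}"
                    )

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)

    @property
    def anchor_position(self) -> int:
        return self.cpg_positions[self.target_index]


@dataclass(frozen=True)
class RegionPanel:
    """An ordered collection of amplicon regions with unique region ids."""

    regions: tuple[AmpliconRegion, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise PanelError(f"duplicate region ids in panel: {ids}")

    @property
    def region_ids(self) -> tuple[str, ...]:
        return tuple(r.region_id for r in self.regions)

    @property
    def score_direction(self) -> dict[str, str]:
        """anchor_cpg -> direction, as used by the AML-score."""
        return {r.anchor_cpg: r.direction for r in self.regions}

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def region(self, region_id: str) -> AmpliconRegion:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(f"region {region_id!r} not in panel")


@dataclass(frozen=True)
class ReadPattern:
    """One collapsed read pattern: a binary methylation vector with multiplicity.

    ``bits`` holds 0 (unmethylated) / 1 (methylated) per CpG, ordered by
    genomic position.  ``count`` is the number of identical reads collapsed
    into this record.  ``allele_bases`` optionally carries the base observed
    at each annotated SNP position.
    """

    sample_id: str
    region_id: str
    bits: tuple[int, ...]
    count: int = 1
    allele_bases: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        bits = tuple(int(b) for b in self.bits)
        if any(b not in (0, 1) for b in bits):
            raise ValidationError(
                f"pattern bits must be 0/1, got {self.bits!r} "
                f"(sample {self.sample_id}, region {self.region_id})"
            )
        object.__setattr__(self, "bits", bits)
        if self.count < 1:
            raise ValidationError(f"pattern count must be >= 1, got {self.count}")
        object.__setattr__(
            self, "allele_bases", tuple(sorted((int(p), str(b)) for p, b in self.allele_bases))
        )

    @property
    def pattern(self) -> str:
        return "".join(str(b) for b in self.bits)

    def base_at(self, snp_position: int) -> str | None:
        for pos, base in self.allele_bases:
            if pos == snp_position:
                return base
        return None


def collapse_patterns(patterns: Iterable[ReadPattern]) -> list[ReadPattern]:
    """Merge identical (bits, allele_bases) records additively; deterministic order."""
    acc: dict[tuple, dict] = {}
    for p in patterns:
        key = (p.sample_id, p.region_id, p.bits, p.allele_bases)
        if key in acc:
            acc[key]["count"] += p.count
        else:
            acc[key] = {
                "sample_id": p.sample_id,
                "region_id": p.region_id,
                "bits": p.bits,
                "count": p.count,
                "allele_bases": p.allele_bases,
            }
    out = [ReadPattern(**v) for v in sorted(acc.values(), key=lambda v: (v["bits"], v["allele_bases"]))]
    return out


@dataclass
class SampleReads:
    """All collapsed read patterns of one sample, keyed by region."""

    sample_id: str
    patterns: dict[str, list[ReadPattern]] = field(default_factory=dict)
    qc_pass: bool | None = None

    def depth(self, region_id: str) -> int:
        return sum(p.count for p in self.patterns.get(region_id, []))

    @property
    def depths(self) -> dict[str, int]:
        return {rid: self.depth(rid) for rid in self.patterns}

    def add(self, pattern: ReadPattern) -> None:
        self.patterns.setdefault(pattern.region_id, []).append(pattern)

    def collapse(self) -> None:
        for rid in self.patterns:
            self.patterns[rid] = collapse_patterns(self.patterns[rid])


@dataclass
class AnomalyResult:
    """Per-sample output of an anomaly method.

    ``ratios`` maps region_id to the fraction of that region's reads called
    abnormal; ``score`` is the arithmetic mean of the available region ratios;
    the sample is ``call == 'positive'`` iff ``score > cutoff``.
    """

    sample_id: str
    ratios: dict[str, float]
    score: float
    cutoff: float
    call: str
    method: str = ""

    def __post_init__(self) -> None:
        for rid, r in self.ratios.items():
            if not 0.0 <= r <= 1.0:
                raise ValidationError(f"anomaly ratio for {rid} outside [0,1]: {r}")
        if self.call not in ("positive", "negative"):
            raise ValidationError(f"call must be positive/negative, got {self.call!r}")


# --------------------------------------------------------------------------
# Region-panel configuration IO
# --------------------------------------------------------------------------

_REGION_FIELDS = {"region_id", "anchor_cpg", "chrom", "cpg_positions", "target_index", "direction"}


def _region_from_mapping(rec: Mapping, idx: int) -> AmpliconRegion:
    if not isinstance(rec, Mapping):
        raise PanelError(f"region #{idx}: expected a mapping, got {type(rec).__name__}")
    missing = _REGION_FIELDS - set(rec)
    if missing:
        raise PanelError(f"region #{idx}: missing field(s) {sorted(missing)}")
    try:
        return AmpliconRegion(
            region_id=str(rec["region_id"]),
            anchor_cpg=str(rec["anchor_cpg"]),
            chrom=str(rec["chrom"]),
            cpg_positions=tuple(rec["cpg_positions"]),
            target_index=int(rec["target_index"]),
            direction=str(rec["direction"]),
            snp_positions=tuple(rec.get("snp_positions") or ()),
        )
    except (TypeError, ValueError) as exc:
        raise PanelError(f"region #{idx}: {exc}") from exc


def load_region_panel(path: str | Path) -> RegionPanel:
    """Load and validate a region panel from a YAML configuration file.

    Schema: a top-level mapping with key ``regions`` holding a list of
    records, each with the fields of :class:`AmpliconRegion`.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise PanelError(f"cannot parse panel file {path}: {exc}") from exc
    if not isinstance(doc, Mapping) or "regions" not in doc:
        raise PanelError(f"panel file {path} must contain a top-level 'regions' list")
    regions = [_region_from_mapping(rec, i) for i, rec in enumerate(doc["regions"])]
    return RegionPanel(tuple(regions))


def write_panel(panel: RegionPanel, path: str | Path) -> None:
    """Write a panel back to the YAML schema accepted by :func:`load_region_panel`."""
    doc = {
        "regions": [
            {
                "region_id": r.region_id,
                "anchor_cpg": r.anchor_cpg,
                "chrom": r.chrom,
                "cpg_positions": list(r.cpg_positions),
                "target_index": r.target_index,
                "direction": r.direction,
                "snp_positions": list(r.snp_positions),
            }
            for r in panel
        ]
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def default_panel() -> RegionPanel:
    """The shipped four-region AML panel.

    Four amplicons around cg15289427 (14 CpGs), cg22797031 (10 CpGs),
    cg27630153 (15 CpGs) and cg19586199 (9 CpGs).  Anchor ids, CpG counts,
    aberration directions and the two annotated SNPs (rs115701567 at
    chr16:88844998, rs917911737 at chr19:14225172) are real; per-CpG genomic
    positions are synthetic placeholders (see the comment in the shipped
    file) pending primer-level coordinates.
    """
    with resources.as_file(resources.files("epimrd.data") / "default_panel.yaml") as p:
        return load_region_panel(p)


# --------------------------------------------------------------------------
# Beta matrix
# --------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """CpG-by-sample methylation beta values with a control/AML partition.

    ``values`` is a DataFrame indexed by CpG id with one column per sample;
    entries are beta values in [0, 1], NaN for missing.  ``group`` maps every
    sample id to ``"control"`` or ``"aml"``.  Missing betas are excluded
    pairwise from means and standard deviations, never imputed.
    """

    values: pd.DataFrame
    group: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate CpG ids: {dups[:5]}")
        arr = self.values.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            i, j = np.argwhere(bad & ~np.isnan(arr))[0]
            raise ValidationError(
                f"beta outside [0,1] at CpG {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}: {arr[i, j]}"
            )
        missing = [s for s in self.values.columns if s not in self.group]
        if missing:
            raise ValidationError(f"samples missing from group map: {missing[:5]}")
        bad_groups = {g for g in self.group.values()} - {"control", "aml"}
        if bad_groups:
            raise ValidationError(f"unknown group label(s): {sorted(bad_groups)}")

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group[s] == group]

    def restrict(self, group: str) -> "BetaMatrix":
        cols = self.samples_in(group)
        return BetaMatrix(self.values[cols], {s: self.group[s] for s in cols})


def load_beta_matrix(path: str | Path, groups: str | Path) -> BetaMatrix:
    """Read a beta matrix TSV (first column CpG id, header row of sample ids)
    and a two-column group map TSV (sample_id, group)."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    if values.shape[0] == 0:
        raise ValidationError(f"no CpGs in {path}")
    gmap = pd.read_csv(groups, sep="\t", header=None, names=["sample_id", "group"])
    group = dict(zip(gmap["sample_id"].astype(str), gmap["group"].astype(str)))
    values.columns = [str(c) for c in values.columns]
    return BetaMatrix(values, group)
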