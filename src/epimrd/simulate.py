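"""Synthetic data generators emulating the structure of the real inputs.

Three substrates are generated, all fully seeded:

* **beta matrices** with planted aberrant CpGs among null CpGs, for testing
  candidate selection;
* **amplicon read sets**: healthy reads are near-binary (per-CpG error rate
  ε, default 0.02, approximating bisulfite-conversion failure plus
  sequencing error, independently per CpG), while aberrant reads flip the
  whole amplicon coherently — one draw decides the read, emulating clonal
  whole-amplicon epiallele aberrations;
* **clonal mixtures**: limiting-dilution samples where each read is aberrant
  with probability f, and heterozygous-SNP samples where each read carries
  one of two allele bases with its allele's methylation profile.

Ground truth (planted CpG ids, realized aberrant-read fractions, per-read
alleles) is always returned alongside the data so downstream recovery can be
tested exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    HYPER,
    BetaMatrix,
    AmpliconRegion,
    ReadPattern,
    RegionPanel,
    SampleReads,
    ValidationError,
    collapse_patterns,
)

__all__ = [
    "CloneProfile",
    "DilutionDesign",
    "simulate_beta_matrix",
    "simulate_reads",
    "simulate_sample",
    "simulate_dilution",
    "simulate_het_sample",
]

DEFAULT_EPS = 0.02


@dataclass(frozen=True)
class CloneProfile:
    """Per-region, per-CpG methylation probabilities of one clone.

    ``coherent=True`` couples all CpGs of a read through a single uniform
    draw (bit_i = 1 iff u < p_i), preserving per-CpG marginals while making
    whole-amplicon aberrations read-coherent; ``coherent=False`` draws CpGs
    independently.
    """

    probs: dict[str, np.ndarray]
    label: str  # "normal" | "aberrant"
    coherent: bool = False

    def __post_init__(self) -> None:
        for rid, p in self.probs.items():
            p = np.asarray(p, dtype=float)
            if np.any((p < 0) | (p > 1)):
                raise ValidationError(f"profile probabilities for {rid} outside [0,1]")
            object.__setattr__(self, "probs", {**self.probs, rid: p})

    @classmethod
    def healthy(cls, panel: RegionPanel, eps: float = DEFAULT_EPS) -> "CloneProfile":
        """Healthy blood: hyper_in_aml regions unmethylated (p=ε), hypo_in_aml
        regions methylated (p=1−ε); independent per-CpG noise."""
        if not 0 <= eps < 0.5:
            raise ValidationError(f"eps must be in [0, 0.5), got {eps}")
        probs = {
            r.region_id: np.full(r.n_cpgs, eps if r.direction == HYPER else 1.0 - eps)
            for r in panel
        }
        return cls(probs=probs, label="normal", coherent=False)

    @classmethod
    def aberrant(cls, panel: RegionPanel, eps: float = DEFAULT_EPS) -> "CloneProfile":
        """Leukemic clone: the opposite extreme of healthy in every region,
        with coherent whole-read aberration."""
        if not 0 <= eps < 0.5:
            raise ValidationError(f"eps must be in [0, 0.5), got {eps}")
        probs = {
            r.region_id: np.full(r.n_cpgs, 1.0 - eps if r.direction == HYPER else eps)
            for r in panel
        }
        return cls(probs=probs, label="aberrant", coherent=True)


@dataclass(frozen=True)
class DilutionDesign:
    """Limiting-dilution series: aberrant-DNA fractions, depth, seed."""

    fractions: tuple[float, ...] = (1.0, 0.5, 0.25, 0.10, 0.05, 0.01, 0.0)
    reads_per_region: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        fr = tuple(float(f) for f in self.fractions)
        if any(not 0 <= f <= 1 for f in fr):
            raise ValidationError("dilution fractions must be in [0,1]")
        if any(b > a for a, b in zip(fr, fr[1:])):
            raise ValidationError("dilution fractions must be sorted descending")
        object.__setattr__(self, "fractions", fr)


def simulate_beta_matrix(
    n_null: int = 480,
    n_planted_hyper: int = 10,
    n_planted_hypo: int = 10,
    n_controls: int = 50,
    n_aml: int = 20,
    effect: float = 0.5,
    noise_sd: float = 0.03,
    seed: int = 0,
) -> tuple[BetaMatrix, list[str]]:
    """Beta matrix with planted AML-aberrant CpGs among null CpGs.

    Null CpGs share a group-independent mean drawn uniformly on [0.05, 0.95].
    Planted hyper CpGs have control mean 0.05 and AML mean 0.05 + effect;
    planted hypo CpGs control mean 0.95 and AML mean 0.95 − effect.  Gaussian
    noise with s.d. ``noise_sd``, clipped to [0, 1].  Returns the matrix and
    the planted CpG ids (hyper first).
    """
    if not 0 < effect <= 1:
        raise ValidationError(f"effect must be in (0,1], got {effect}")
    rng = np.random.default_rng(seed)
    n_cpg = n_null + n_planted_hyper + n_planted_hypo
    ctrl_mean = np.empty(n_cpg)
    aml_mean = np.empty(n_cpg)
    ctrl_mean[:n_null] = aml_mean[:n_null] = rng.uniform(0.05, 0.95, size=n_null)
    hy = slice(n_null, n_null + n_planted_hyper)
    ho = slice(n_null + n_planted_hyper, n_cpg)
    ctrl_mean[hy] = 0.05
    aml_mean[hy] = 0.05 + effect
    ctrl_mean[ho] = 0.95
    aml_mean[ho] = 0.95 - effect
    ctrl = np.clip(
        ctrl_mean[:, None] + rng.normal(0, noise_sd, size=(n_cpg, n_controls)), 0, 1
    )
    aml = np.clip(aml_mean[:, None] + rng.normal(0, noise_sd, size=(n_cpg, n_aml)), 0, 1)
    cpg_ids = [f"cg{i:08d}" for i in range(n_cpg)]
    sample_ids = [f"ctrl{i:03d}" for i in range(n_controls)] + [
        f"aml{i:03d}" for i in range(n_aml)
    ]
    values = pd.DataFrame(np.hstack([ctrl, aml]), index=cpg_ids, columns=sample_ids)
    group = {s: ("control" if s.startswith("ctrl") else "aml") for s in sample_ids}
    planted = cpg_ids[n_null:]
    return BetaMatrix(values, group), planted


def _draw_patterns(
    probs: np.ndarray, n_reads: int, coherent: bool, rng: np.random.Generator
) -> np.ndarray:
    if coherent:
        u = rng.uniform(size=(n_reads, 1))
        return (u < probs[None, :]).astype(int)
    return (rng.uniform(size=(n_reads, probs.size)) < probs[None, :]).astype(int)


def _collapse_rows(
    bits: np.ndarray,
    sample_id: str,
    region_id: str,
    allele_bases: tuple[tuple[int, str], ...] = (),
) -> list[ReadPattern]:
    uniq, counts = np.unique(bits, axis=0, return_counts=True)
    return [
        ReadPattern(sample_id, region_id, tuple(int(b) for b in row), int(c), allele_bases)
        for row, c in zip(uniq, counts)
    ]


def simulate_reads(
    profile: CloneProfile,
    region: AmpliconRegion,
    n_reads: int,
    seed: int = 0,
    sample_id: str = "sim",
) -> list[ReadPattern]:
    """Draw ``n_reads`` reads for one region from a clone profile, collapsed."""
    rng = np.random.default_rng(seed)
    bits = _draw_patterns(profile.probs[region.region_id], n_reads, profile.coherent, rng)
    return _collapse_rows(bits, sample_id, region.region_id)


def simulate_sample(
    profile: CloneProfile,
    panel: RegionPanel,
    reads_per_region: int,
    seed: int = 0,
    sample_id: str = "sim",
) -> SampleReads:
    """A whole-panel sample drawn from a single clone profile."""
    rng = np.random.default_rng(seed)
    sample = SampleReads(sample_id)
    for region in panel:
        bits = _draw_patterns(
            profile.probs[region.region_id], reads_per_region, profile.coherent, rng
        )
        sample.patterns[region.region_id] = _collapse_rows(bits, sample_id, region.region_id)
    return sample


def simulate_dilution(
    normal: CloneProfile,
    aberrant: CloneProfile,
    panel: RegionPanel,
    design: DilutionDesign,
    sample_prefix: str = "dil",
) -> list[tuple[SampleReads, float, dict[str, float]]]:
    """Limiting-dilution series of clonal mixtures.

    At nominal fraction f each read is independently aberrant with
    probability f.  Returns, per dilution step, the sample, its nominal
    fraction, and the realized aberrant-read fraction per region (ground
    truth for recovery tests).
    """
    rng = np.random.default_rng(design.seed)
    out = []
    for f in design.fractions:
        sid = f"{sample_prefix}_f{f:g}"
        sample = SampleReads(sid)
        realized: dict[str, float] = {}
        for region in panel:
            is_ab = rng.uniform(size=design.reads_per_region) < f
            n_ab = int(is_ab.sum())
            realized[region.region_id] = n_ab / design.reads_per_region
            parts = []
            if design.reads_per_region - n_ab:
                parts.append(
                    _draw_patterns(
                        normal.probs[region.region_id],
                        design.reads_per_region - n_ab,
                        normal.coherent,
                        rng,
                    )
                )
            if n_ab:
                parts.append(
                    _draw_patterns(
                        aberrant.probs[region.region_id], n_ab, aberrant.coherent, rng
                    )
                )
            sample.patterns[region.region_id] = _collapse_rows(
                np.vstack(parts), sid, region.region_id
            )
        out.append((sample, f, realized))
    return out


def simulate_het_sample(
    profile_a: CloneProfile,
    profile_b: CloneProfile,
    region: AmpliconRegion,
    snp_position: int,
    bases: tuple[str, str] = ("A", "G"),
    n_reads: int = 2000,
    seed: int = 0,
    sample_id: str = "het",
) -> SampleReads:
    """A heterozygous sample: each read gets allele a or b with probability
    1/2, its pattern drawn from that allele's profile, and the allele base
    recorded at the SNP position."""
    if snp_position not in region.snp_positions:
        raise ValidationError(
            f"position {snp_position} is not an annotated SNP of region {region.region_id!r}"
        )
    rng = np.random.default_rng(seed)
    is_a = rng.uniform(size=n_reads) < 0.5
    sample = SampleReads(sample_id)
    for allele_mask, profile, base in ((is_a, profile_a, bases[0]), (~is_a, profile_b, bases[1])):
        n = int(allele_mask.sum())
        if n == 0:
            continue
        bits = _draw_patterns(profile.probs[region.region_id], n, profile.coherent, rng)
        for p in _collapse_rows(bits, sample_id, region.region_id, ((snp_position, base),)):
            sample.add(p)
    return sample
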