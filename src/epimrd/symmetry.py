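"""Allele-specific methylation analysis inside an amplicon.

A heterozygous SNP inside an amplicon (at least 3 bp from every CpG, so the
variant cannot be a bisulfite artefact) lets every read be assigned to one
of the two parental alleles.  Splitting a sample's reads by that base and
comparing the per-CpG methylation levels and the whole-pattern frequency
distributions of the two groups quantifies whether aberrant methylation is
symmetric across homologous chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import AmpliconRegion, ReadPattern, ValidationError

__all__ = ["AlleleSplit", "SymmetryStat", "detect_het_snp", "split_by_allele", "symmetry_stat"]

MIN_MINOR = 0.3  # "around 50%": both top variants must carry >= 30% of calls
MIN_GROUP_READS = 50


@dataclass
class AlleleSplit:
    """Reads of one sample partitioned by the base at a heterozygous SNP."""

    snp_position: int
    allele_a_base: str
    allele_b_base: str
    reads_a: list[ReadPattern]
    reads_b: list[ReadPattern]
    discarded: int  # reads with a third base or no call at the SNP

    @property
    def minor_fraction(self) -> float:
        na = sum(p.count for p in self.reads_a)
        nb = sum(p.count for p in self.reads_b)
        return min(na, nb) / (na + nb)


@dataclass
class SymmetryStat:
    """Per-CpG beta differences and pattern-distribution distance between alleles."""

    per_cpg_delta: np.ndarray  # |beta_a - beta_b| per CpG, each in [0, 1]
    max_delta: float
    l1_pattern_distance: float  # total variation distance of pattern frequencies, in [0, 1]


def detect_het_snp(
    reads: Sequence[ReadPattern], region: AmpliconRegion, min_minor: float = MIN_MINOR
) -> int | None:
    """Find an annotated SNP position that is heterozygous in this sample.

    A position qualifies when the top two base frequencies among reads with a
    call there are each at least ``min_minor`` (default 0.3 — "around 50%"
    with tolerance for allele-specific amplification bias).  The 3-bp
    distance from CpGs is already enforced by panel validation.  Returns the
    first qualifying position in annotation order, or None.
    """
    for snp in region.snp_positions:
        counts: dict[str, int] = {}
        for p in reads:
            base = p.base_at(snp)
            if base is not None:
                counts[base] = counts.get(base, 0) + p.count
        total = sum(counts.values())
        if total == 0 or len(counts) < 2:
            continue
        top2 = sorted(counts.values(), reverse=True)[:2]
        if all(c / total >= min_minor for c in top2):
            return snp
    return None


def split_by_allele(reads: Sequence[ReadPattern], snp_position: int) -> AlleleSplit:
    """Partition reads by the base at a heterozygous SNP.

    The two most frequent bases define the alleles (ties broken
    alphabetically); reads carrying a third base or no call there are
    discarded and tallied, so |a| + |b| + discarded equals the input count.
    """
    counts: dict[str, int] = {}
    for p in reads:
        base = p.base_at(snp_position)
        if base is not None:
            counts[base] = counts.get(base, 0) + p.count
    if len(counts) < 2:
        raise ValidationError(
            f"fewer than two bases observed at position {snp_position}; not heterozygous"
        )
    ranked = sorted(counts, key=lambda b: (-counts[b], b))
    base_a, base_b = ranked[:2]
    reads_a = [p for p in reads if p.base_at(snp_position) == base_a]
    reads_b = [p for p in reads if p.base_at(snp_position) == base_b]
    discarded = sum(
        p.count for p in reads if p.base_at(snp_position) not in (base_a, base_b)
    )
    return AlleleSplit(
        snp_position=snp_position,
        allele_a_base=base_a,
        allele_b_base=base_b,
        reads_a=reads_a,
        reads_b=reads_b,
        discarded=discarded,
    )


def _betas(reads: Sequence[ReadPattern]) -> np.ndarray:
    X = np.array([p.bits for p in reads], dtype=float)
    w = np.array([p.count for p in reads], dtype=float)
    return (w[:, None] * X).sum(axis=0) / w.sum()


def _pattern_freqs(reads: Sequence[ReadPattern]) -> dict[str, float]:
    total = sum(p.count for p in reads)
    freqs: dict[str, float] = {}
    for p in reads:
        freqs[p.pattern] = freqs.get(p.pattern, 0.0) + p.count / total
    return freqs


def symmetry_stat(split: AlleleSplit, min_reads: int = MIN_GROUP_READS) -> SymmetryStat:
    """Quantify methylation symmetry between the two alleles.

    Reports both the per-CpG |Δβ| between alleles (marginal view) and half
    the L1 distance between the two count-normalised pattern frequency
    distributions (whole-epiallele view; 0 = identical, 1 = disjoint).
    Symmetric under swapping the alleles.
    """
    na = sum(p.count for p in split.reads_a)
    nb = sum(p.count for p in split.reads_b)
    if na < min_reads or nb < min_reads:
        raise ValidationError(
            f"allele groups too small ({na}/{nb} reads, need >= {min_reads} each); "
            f"sequence the sample deeper"
        )
    delta = np.abs(_betas(split.reads_a) - _betas(split.reads_b))
    fa = _pattern_freqs(split.reads_a)
    fb = _pattern_freqs(split.reads_b)
    keys = set(fa) | set(fb)
    l1 = 0.5 * sum(abs(fa.get(k, 0.0) - fb.get(k, 0.0)) for k in keys)
    return SymmetryStat(
        per_cpg_delta=delta,
        max_delta=float(delta.max()),
        l1_pattern_distance=float(l1),
    )
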