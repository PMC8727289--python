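"""The four-CpG AML-score.

The score combines direction-adjusted beta values at the four AML-associated
anchor CpGs::

    AML-score = (b_cg15289427 + b_cg22797031
                 + (1 - b_cg27630153) + (1 - b_cg19586199)) / 4

i.e. the mean over anchors of beta for CpGs hypermethylated in AML and
1 − beta for CpGs hypomethylated in AML, so 0 is the healthy archetype and 1
the fully aberrant one.  A sample is called positive when its score exceeds a
cutoff calibrated as a high percentile (default 99.5) of healthy-control
scores; on methylation-array cohorts that calibration lands near 0.125.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._stats import percentile
from .model import HYPER, RegionPanel, SampleReads, ValidationError

__all__ = [
    "AmlScoreResult",
    "compute_aml_score",
    "calibrate_cutoff",
    "classify_sample",
    "baseq_anchor_betas",
    "score_sample_reads",
]

ARRAY_CUTOFF = 0.125  # array-cohort convention for the 99.5th control percentile


@dataclass
class AmlScoreResult:
    sample_id: str
    betas: dict[str, float]
    score: float
    cutoff: float
    call: str


def compute_aml_score(betas: dict[str, float], panel: RegionPanel) -> float:
    """Evaluate the AML-score from anchor-CpG betas.

    Every anchor of the panel must be present with beta in [0, 1].
    """
    direction = panel.score_direction
    missing = [a for a in direction if a not in betas]
    if missing:
        raise ValidationError(f"missing anchor CpG beta(s): {missing}")
    terms = []
    for anchor, d in direction.items():
        b = float(betas[anchor])
        if not 0.0 <= b <= 1.0:
            raise ValidationError(f"beta for {anchor} outside [0,1]: {b}")
        terms.append(b if d == HYPER else 1.0 - b)
    return float(np.mean(terms))


def calibrate_cutoff(control_scores, q: float = 99.5) -> float:
    """Percentile cutoff (linear interpolation) from healthy-control scores.

    Requires at least 10 controls; fewer makes a 99.5th percentile
    meaningless.
    """
    scores = np.asarray(control_scores, dtype=float)
    if scores.size < 10:
        raise ValidationError(
            f"need >= 10 control scores to calibrate a cutoff, got {scores.size}"
        )
    return percentile(scores, q)


def classify_sample(score: float, cutoff: float) -> str:
    """'positive' iff score is strictly above the cutoff."""
    return "positive" if score > cutoff else "negative"


def baseq_anchor_betas(
    reads: SampleReads, panel: RegionPanel, amplicon_mean: bool = False
) -> dict[str, float]:
    """Anchor-CpG betas of one BA-seq sample.

    Default: beta at an anchor is the count-weighted methylated-read fraction
    at the region's target CpG column.  With ``amplicon_mean=True`` the mean
    methylation over all CpGs of the amplicon is used instead (exposed as a
    variant; the score is defined on the anchor CpGs).
    """
    betas: dict[str, float] = {}
    for region in panel:
        patterns = reads.patterns.get(region.region_id, [])
        total = sum(p.count for p in patterns)
        if total == 0:
            raise ValidationError(
                f"sample {reads.sample_id!r}: no reads for region "
                f"{region.region_id!r}; AML-score undefined without all anchors"
            )
        if amplicon_mean:
            meth = sum(p.count * float(np.mean(p.bits)) for p in patterns)
        else:
            meth = sum(p.count * p.bits[region.target_index] for p in patterns)
        betas[region.anchor_cpg] = meth / total
    return betas


def score_sample_reads(
    reads: SampleReads, panel: RegionPanel, cutoff: float, amplicon_mean: bool = False
) -> AmlScoreResult:
    """Compute anchor betas, AML-score and call for one BA-seq sample."""
    betas = baseq_anchor_betas(reads, panel, amplicon_mean=amplicon_mean)
    score = compute_aml_score(betas, panel)
    return AmlScoreResult(
        sample_id=reads.sample_id,
        betas=betas,
        score=score,
        cutoff=cutoff,
        call=classify_sample(score, cutoff),
    )
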