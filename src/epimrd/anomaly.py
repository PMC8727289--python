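"""Aggregation shared by the read-level anomaly detectors.

Both the random-forest and the autoencoder detectors classify individual
reads as normal or abnormal per region.  The per-region *anomaly ratio* is
the count-weighted fraction of abnormal reads; the per-sample *anomaly
score* is the arithmetic mean of the available region ratios; the sample
cutoff is the 99th percentile of the control training samples' scores, and a
sample is called positive when its score is strictly above it.
"""

from __future__ import annotations

import logging

import numpy as np

from ._stats import percentile
from .model import AnomalyResult, ValidationError
from .score import classify_sample

logger = logging.getLogger(__name__)

__all__ = ["anomaly_score", "calibrate_anomaly_cutoff", "build_result"]

ANOMALY_PERCENTILE = 99.0


def anomaly_score(ratios: dict[str, float]) -> float:
    """Mean of the available region anomaly ratios."""
    vals = [r for r in ratios.values() if r is not None]
    if not vals:
        raise ValidationError("no region anomaly ratios available for this sample")
    if len(vals) < len(ratios):
        logger.warning("anomaly score computed from %d of %d regions", len(vals), len(ratios))
    return float(np.mean(vals))


def calibrate_anomaly_cutoff(control_train_scores, q: float = ANOMALY_PERCENTILE) -> float:
    """Percentile cutoff (linear interpolation) over control training scores."""
    scores = np.asarray(control_train_scores, dtype=float)
    if scores.size == 0:
        raise ValidationError("no control training scores to calibrate a cutoff")
    return percentile(scores, q)


def build_result(
    sample_id: str, ratios: dict[str, float], cutoff: float, method: str
) -> AnomalyResult:
    available = {rid: r for rid, r in ratios.items() if r is not None}
    score = anomaly_score(available)
    return AnomalyResult(
        sample_id=sample_id,
        ratios=available,
        score=score,
        cutoff=cutoff,
        call=classify_sample(score, cutoff),
        method=method,
    )
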