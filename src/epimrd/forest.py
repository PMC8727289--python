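"""Supervised read-level anomaly detection with a depth-limited random forest.

One forest per amplicon region.  Features are the region's CpG bit columns;
every read of a control training sample is labelled *normal* and every read
of an AML first-diagnosis sample *abnormal*.  This is deliberate label
noise: diagnosis samples contain normal blood reads too, but the majority
signal suffices for the forest to carve out the aberrant pattern space.
Trees are limited to depth 5; 100 trees with class-balanced, count-aware
sample weights (the labels are heavily imbalanced towards control reads).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .anomaly import build_result, calibrate_anomaly_cutoff
from .model import AnomalyResult, AmpliconRegion, ReadPattern, RegionPanel, SampleReads, ValidationError

__all__ = ["ForestParams", "ForestModel", "train_forest", "anomaly_ratio", "PanelForest"]

NORMAL, ABNORMAL = 0, 1


@dataclass(frozen=True)
class ForestParams:
    n_trees: int = 100
    max_depth: int = 5
    seed: int = 0


@dataclass
class ForestModel:
    """A trained per-region forest plus its training metadata."""

    region_id: str
    params: ForestParams
    classifier: RandomForestClassifier
    n_train_normal: int = 0
    n_train_abnormal: int = 0

    def predict_abnormal(self, bits_matrix: np.ndarray) -> np.ndarray:
        return self.classifier.predict(bits_matrix) == ABNORMAL


def _pattern_matrix(reads: Sequence[ReadPattern], region: AmpliconRegion) -> tuple[np.ndarray, np.ndarray]:
    for p in reads:
        if len(p.bits) != region.n_cpgs:
            raise ValidationError(
                f"pattern length {len(p.bits)} != {region.n_cpgs} CpGs of region "
                f"{region.region_id!r} (sample {p.sample_id!r})"
            )
    X = np.array([p.bits for p in reads], dtype=float)
    w = np.array([p.count for p in reads], dtype=float)
    return X, w


def train_forest(
    control_train_reads: Sequence[ReadPattern],
    aml_diagnosis_reads: Sequence[ReadPattern],
    region: AmpliconRegion,
    params: ForestParams | None = None,
) -> ForestModel:
    """Fit the per-region forest on labelled collapsed read patterns.

    Sample weights are pattern counts rescaled so both classes carry equal
    total weight.  Deterministic for a fixed seed.
    """
    params = params or ForestParams()
    if not control_train_reads or not aml_diagnosis_reads:
        raise ValidationError(
            f"region {region.region_id!r}: both normal and abnormal training reads "
            f"are required (got {len(control_train_reads)} / {len(aml_diagnosis_reads)})"
        )
    Xn, wn = _pattern_matrix(control_train_reads, region)
    Xa, wa = _pattern_matrix(aml_diagnosis_reads, region)
    X = np.vstack([Xn, Xa])
    y = np.concatenate([np.full(len(Xn), NORMAL), np.full(len(Xa), ABNORMAL)])
    total = wn.sum() + wa.sum()
    # balance: each class contributes half of the total weight
    w = np.concatenate([wn * (total / 2.0 / wn.sum()), wa * (total / 2.0 / wa.sum())])
    clf = RandomForestClassifier(
        n_estimators=params.n_trees,
        max_depth=params.max_depth,
        random_state=params.seed,
    )
    clf.fit(X, y, sample_weight=w)
    return ForestModel(
        region_id=region.region_id,
        params=params,
        classifier=clf,
        n_train_normal=int(wn.sum()),
        n_train_abnormal=int(wa.sum()),
    )


def anomaly_ratio(model: ForestModel, reads: Sequence[ReadPattern], region: AmpliconRegion) -> float | None:
    """Count-weighted fraction of a sample's region reads classified abnormal.

    Returns None when the sample has no reads for the region (the region is
    then missing from the sample's ratios).
    """
    if not reads:
        return None
    X, w = _pattern_matrix(reads, region)
    abnormal = model.predict_abnormal(X)
    return float(w[abnormal].sum() / w.sum())


@dataclass
class PanelForest:
    """Forests for every panel region plus a calibrated sample-level cutoff."""

    panel: RegionPanel
    models: dict[str, ForestModel]
    cutoff: float = float("nan")

    @classmethod
    def train(
        cls,
        control_train: Sequence[SampleReads],
        aml_diagnosis: Sequence[SampleReads],
        panel: RegionPanel,
        params: ForestParams | None = None,
        restrict_to: set[str] | None = None,
    ) -> "PanelForest":
        """Train per-region forests and calibrate the 99th-percentile cutoff
        on the control training samples' own anomaly scores.

        ``restrict_to`` optionally limits the abnormal class to a subset of
        diagnosis sample ids (e.g. only NPM1-mutated diagnoses when the MRD
        follow-ups being classified all stem from NPM1-mutated disease).
        """
        if restrict_to is not None:
            aml_diagnosis = [s for s in aml_diagnosis if s.sample_id in restrict_to]
        models = {}
        for region in panel:
            ctrl = [p for s in control_train for p in s.patterns.get(region.region_id, [])]
            aml = [p for s in aml_diagnosis for p in s.patterns.get(region.region_id, [])]
            models[region.region_id] = train_forest(ctrl, aml, region, params)
        pf = cls(panel=panel, models=models)
        train_scores = [pf.classify(s).score for s in control_train]
        pf.cutoff = calibrate_anomaly_cutoff(train_scores)
        return pf

    def classify(self, sample: SampleReads) -> AnomalyResult:
        ratios = {
            region.region_id: anomaly_ratio(
                self.models[region.region_id],
                sample.patterns.get(region.region_id, []),
                region,
            )
            for region in self.panel
        }
        cutoff = 0.0 if np.isnan(self.cutoff) else self.cutoff
        return build_result(sample.sample_id, ratios, cutoff, method="rf")
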