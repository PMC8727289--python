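"""End-to-end benchmark and dilution evaluation on synthetic cohorts.

``run_benchmark`` mirrors the four-way method comparison (AML-score, random
forest, autoencoder without clustering, autoencoder with clustering): all
methods share one QC pass, one control train/validation split and one
training set, and each produces per-sample scores, calls and a confusion
matrix against ground truth.  ``run_dilution_eval`` runs a seeded
limiting-dilution series through every method and reports the smallest
aberrant-DNA fraction each method detects reliably.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .autoencoder import AutoencoderParams, PanelAutoencoder
from .forest import ForestParams, PanelForest
from .model import RegionPanel, SampleReads, ValidationError
from .reads import SplitSpec, qc_filter, split_controls
from .score import calibrate_cutoff, score_sample_reads
from .simulate import CloneProfile, DilutionDesign, simulate_dilution, simulate_sample

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "MethodOutput",
    "BenchmarkResult",
    "synthetic_cohort",
    "run_benchmark",
    "run_dilution_eval",
    "DilutionReport",
]

ALL_METHODS = ("aml_score", "rf", "ae", "ae_cluster")


@dataclass(frozen=True)
class RunConfig:
    """Shared run settings for the benchmark and dilution evaluations."""

    methods: tuple[str, ...] = ALL_METHODS
    seed: int = 0
    min_depth: int = 50
    train_fraction: float = 0.7
    aml_score_percentile: float = 99.5
    anomaly_percentile: float = 99.0
    n_clusters: int = 5
    fixed_aml_cutoff: float | None = None  # e.g. 0.125 array-cohort convention

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValidationError(f"unknown method(s): {sorted(unknown)}")


@dataclass
class MethodOutput:
    method: str
    cutoff: float
    scores: dict[str, float]  # sample_id -> score
    calls: dict[str, str]  # sample_id -> positive/negative
    confusion: dict[str, int] = field(default_factory=dict)  # tp/fp/tn/fn


@dataclass
class BenchmarkResult:
    methods: dict[str, MethodOutput]
    excluded_samples: list[str]
    n_train: int
    n_validation: int


def synthetic_cohort(
    panel: RegionPanel,
    n_normal: int,
    n_aberrant: int,
    reads_per_region: int = 400,
    eps: float = 0.02,
    seed: int = 0,
    prefix: str = "s",
) -> tuple[list[SampleReads], dict[str, str]]:
    """Generate pure healthy and pure leukemia-like samples with truth labels."""
    healthy = CloneProfile.healthy(panel, eps)
    aberrant = CloneProfile.aberrant(panel, eps)
    samples: list[SampleReads] = []
    truth: dict[str, str] = {}
    rng = np.random.default_rng(seed)
    for i in range(n_normal):
        sid = f"{prefix}_normal{i:03d}"
        samples.append(
            simulate_sample(healthy, panel, reads_per_region, seed=int(rng.integers(2**31)), sample_id=sid)
        )
        truth[sid] = "normal"
    for i in range(n_aberrant):
        sid = f"{prefix}_abnormal{i:03d}"
        samples.append(
            simulate_sample(aberrant, panel, reads_per_region, seed=int(rng.integers(2**31)), sample_id=sid)
        )
        truth[sid] = "abnormal"
    return samples, truth


@dataclass
class _TrainedMethods:
    aml_cutoff: float | None = None
    forest: PanelForest | None = None
    ae: PanelAutoencoder | None = None
    ae_cluster: PanelAutoencoder | None = None


def _train_methods(
    config: RunConfig,
    panel: RegionPanel,
    control_train: list[SampleReads],
    aml_train: list[SampleReads],
) -> _TrainedMethods:
    tm = _TrainedMethods()
    if "aml_score" in config.methods:
        if config.fixed_aml_cutoff is not None:
            tm.aml_cutoff = config.fixed_aml_cutoff
        else:
            scores = [
                score_sample_reads(s, panel, cutoff=0.0).score for s in control_train
            ]
            tm.aml_cutoff = calibrate_cutoff(scores, config.aml_score_percentile)
    if "rf" in config.methods:
        tm.forest = PanelForest.train(
            control_train, aml_train, panel, ForestParams(seed=config.seed)
        )
    ae_params = AutoencoderParams(seed=config.seed)
    if "ae" in config.methods:
        tm.ae = PanelAutoencoder.train(control_train, panel, n_clusters=1, params=ae_params)
    if "ae_cluster" in config.methods:
        tm.ae_cluster = PanelAutoencoder.train(
            control_train, panel, n_clusters=config.n_clusters, params=ae_params
        )
    return tm


def _classify(
    tm: _TrainedMethods, method: str, panel: RegionPanel, sample: SampleReads
) -> tuple[float, str]:
    if method == "aml_score":
        r = score_sample_reads(sample, panel, cutoff=tm.aml_cutoff)
        return r.score, r.call
    model = {"rf": tm.forest, "ae": tm.ae, "ae_cluster": tm.ae_cluster}[method]
    r = model.classify(sample)
    return r.score, r.call


def _method_cutoff(tm: _TrainedMethods, method: str) -> float:
    return {
        "aml_score": lambda: tm.aml_cutoff,
        "rf": lambda: tm.forest.cutoff,
        "ae": lambda: tm.ae.cutoff,
        "ae_cluster": lambda: tm.ae_cluster.cutoff,
    }[method]()


def run_benchmark(
    controls: Sequence[SampleReads],
    aml_train: Sequence[SampleReads],
    test_samples: Sequence[SampleReads],
    panel: RegionPanel,
    truth: dict[str, str] | None = None,
    config: RunConfig | None = None,
) -> BenchmarkResult:
    """Four-way method comparison on a shared QC pass and train split.

    Validation controls are appended to the evaluated set (labelled
    ``normal`` when truth is given and does not cover them).  Without truth
    labels only scores and calls are reported, no confusion matrices.
    """
    config = config or RunConfig()
    all_in = list(controls) + list(aml_train) + list(test_samples)
    kept, excluded = qc_filter(all_in, panel, config.min_depth)
    kept_ids = {s.sample_id for s in kept}
    controls = [s for s in controls if s.sample_id in kept_ids]
    aml_train = [s for s in aml_train if s.sample_id in kept_ids]
    test_samples = [s for s in test_samples if s.sample_id in kept_ids]

    train, validation = split_controls(
        controls, SplitSpec(config.train_fraction, config.seed)
    )
    tm = _train_methods(config, panel, train, aml_train)

    evaluated = list(validation) + list(test_samples)
    truth = dict(truth or {})
    for s in validation:
        truth.setdefault(s.sample_id, "normal")

    methods: dict[str, MethodOutput] = {}
    for method in config.methods:
        scores: dict[str, float] = {}
        calls: dict[str, str] = {}
        for s in evaluated:
            scores[s.sample_id], calls[s.sample_id] = _classify(tm, method, panel, s)
        confusion: dict[str, int] = {}
        labelled = [s for s in evaluated if s.sample_id in truth]
        if labelled:
            tp = sum(
                1
                for s in labelled
                if truth[s.sample_id] == "abnormal" and calls[s.sample_id] == "positive"
            )
            fn = sum(1 for s in labelled if truth[s.sample_id] == "abnormal") - tp
            fp = sum(
                1
                for s in labelled
                if truth[s.sample_id] == "normal" and calls[s.sample_id] == "positive"
            )
            tn = sum(1 for s in labelled if truth[s.sample_id] == "normal") - fp
            confusion = {"tp": tp, "fn": fn, "fp": fp, "tn": tn}
        methods[method] = MethodOutput(
            method=method,
            cutoff=float(_method_cutoff(tm, method)),
            scores=scores,
            calls=calls,
            confusion=confusion,
        )
    return BenchmarkResult(
        methods=methods,
        excluded_samples=[s.sample_id for s in excluded],
        n_train=len(train),
        n_validation=len(validation),
    )


@dataclass
class DilutionReport:
    """Per-method dilution behaviour across seeds."""

    fractions: tuple[float, ...]
    mean_scores: dict[str, dict[float, float]]  # method -> fraction -> mean score
    positive_rates: dict[str, dict[float, float]]  # method -> fraction -> P(call positive)
    detection_limit: dict[str, float | None]  # smallest reliably detected fraction
    n_seeds: int


def run_dilution_eval(
    panel: RegionPanel,
    design: DilutionDesign | None = None,
    n_seeds: int = 10,
    n_controls: int = 300,
    n_aml_train: int = 10,
    eps: float = 0.02,
    config: RunConfig | None = None,
    min_positive_rate: float = 0.95,
) -> DilutionReport:
    """Detection-limit study: train per seed, classify a dilution series.

    For every seed a fresh control cohort is generated, methods are trained
    (and calibrated) on its training split, and the dilution series is
    classified.  The detection limit of a method is the smallest nonzero
    fraction f such that the method calls positive in at least
    ``min_positive_rate`` of seeds at f and at every larger fraction.
    """
    design = design or DilutionDesign()
    config = config or RunConfig()
    healthy = CloneProfile.healthy(panel, eps)
    aberrant = CloneProfile.aberrant(panel, eps)

    scores: dict[str, dict[float, list[float]]] = {
        m: {f: [] for f in design.fractions} for m in config.methods
    }
    positives: dict[str, dict[float, list[bool]]] = {
        m: {f: [] for f in design.fractions} for m in config.methods
    }
    for s in range(n_seeds):
        seed = (config.seed + 7919 * s) % (2**31)
        rng = np.random.default_rng(seed)
        controls = [
            simulate_sample(
                healthy,
                panel,
                design.reads_per_region,
                seed=int(rng.integers(2**31)),
                sample_id=f"ctrl{i:03d}",
            )
            for i in range(n_controls)
        ]
        aml_train = [
            simulate_sample(
                aberrant,
                panel,
                design.reads_per_region,
                seed=int(rng.integers(2**31)),
                sample_id=f"aml{i:03d}",
            )
            for i in range(n_aml_train)
        ]
        train, _ = split_controls(
            controls, SplitSpec(config.train_fraction, int(rng.integers(2**31)))
        )
        seed_config = RunConfig(
            methods=config.methods,
            seed=seed,
            min_depth=config.min_depth,
            train_fraction=config.train_fraction,
            aml_score_percentile=config.aml_score_percentile,
            anomaly_percentile=config.anomaly_percentile,
            n_clusters=config.n_clusters,
            fixed_aml_cutoff=config.fixed_aml_cutoff,
        )
        tm = _train_methods(seed_config, panel, train, aml_train)
        series = simulate_dilution(
            healthy,
            aberrant,
            panel,
            DilutionDesign(
                design.fractions, design.reads_per_region, seed=int(rng.integers(2**31))
            ),
        )
        for sample, f, _realized in series:
            for method in config.methods:
                score, call = _classify(tm, method, panel, sample)
                scores[method][f].append(score)
                positives[method][f].append(call == "positive")

    mean_scores = {
        m: {f: float(np.mean(v)) for f, v in per.items()} for m, per in scores.items()
    }
    positive_rates = {
        m: {f: float(np.mean(v)) for f, v in per.items()} for m, per in positives.items()
    }
    detection_limit: dict[str, float | None] = {}
    for m in config.methods:
        limit = None
        for f in design.fractions:  # descending
            if f == 0:
                break
            if positive_rates[m][f] >= min_positive_rate:
                limit = f
            else:
                break
        detection_limit[m] = limit
    return DilutionReport(
        fractions=design.fractions,
        mean_scores=mean_scores,
        positive_rates=positive_rates,
        detection_limit=detection_limit,
        n_seeds=n_seeds,
    )
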