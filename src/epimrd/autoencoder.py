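"""Unsupervised read-level anomaly detection with per-cluster autoencoders.

Reads are encoded as vectors over {−1, +1} (−1 unmethylated, +1 methylated).
Because a blood sample is a mixture of cell types with distinct methylation
landscapes, reads of a region are optionally pre-clustered with K-means
(default K = 5) and one autoencoder is trained per cluster; the no-clustering
variant is the K = 1 special case and therefore identical to it by
construction.

Each autoencoder is a small fully connected network with hidden widths
8-3-8 (encoder, latent, decoder) between input and output layers of width
equal to the region's CpG count, hyperbolic-tangent activations throughout
(including the output layer, since targets are ±1) and mean-squared-error
loss.  A read is *abnormal* when its reconstruction loss exceeds the
cluster's threshold, set at the 99th percentile of the training reads'
losses — so at most ~1% of training reads are flagged by construction.
Training is full-batch gradient descent with adaptive-moment (Adam) updates,
seeded and deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from ._stats import weighted_percentile
from .anomaly import build_result, calibrate_anomaly_cutoff
from .model import AnomalyResult, AmpliconRegion, ReadPattern, RegionPanel, SampleReads, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "AutoencoderParams",
    "ClusterModel",
    "AutoencoderModel",
    "RegionAutoencoders",
    "PanelAutoencoder",
    "encode_reads",
    "fit_clusters",
    "assign_cluster",
    "train_autoencoder",
]


def encode_reads(reads: Sequence[ReadPattern]) -> tuple[np.ndarray, np.ndarray]:
    """Map bit patterns to ±1 vectors (0 → −1, 1 → +1), with their counts."""
    X = np.array([p.bits for p in reads], dtype=float) * 2.0 - 1.0
    w = np.array([p.count for p in reads], dtype=float)
    return X, w


@dataclass(frozen=True)
class AutoencoderParams:
    hidden: tuple[int, int, int] = (8, 3, 8)
    epochs: int = 500
    learning_rate: float = 0.01
    plateau_tol: float = 1e-7  # relative-improvement floor for early stop
    plateau_patience: int = 30
    seed: int = 0


@dataclass
class ClusterModel:
    """K-means centroids for routing a region's reads to autoencoders."""

    region_id: str
    k: int
    centroids: np.ndarray  # (k, n_cpgs), entries in [-1, 1]
    seed: int = 0


def fit_clusters(
    train_reads: Sequence[ReadPattern], region: AmpliconRegion, k: int = 5, seed: int = 0
) -> ClusterModel:
    """Count-weighted K-means on encoded training reads.

    If the training set has fewer distinct patterns than ``k``, the number
    of clusters is reduced with a warning.
    """
    if not train_reads:
        raise ValidationError(f"region {region.region_id!r}: empty training set for clustering")
    X, w = encode_reads(train_reads)
    n_distinct = np.unique(X, axis=0).shape[0]
    if n_distinct < k:
        logger.warning(
            "region %s: only %d distinct patterns, reducing k from %d",
            region.region_id,
            n_distinct,
            k,
        )
        k = n_distinct
    if k == 1:
        centroids = np.average(X, axis=0, weights=w)[None, :]
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        km.fit(X, sample_weight=w)
        centroids = km.cluster_centers_
    return ClusterModel(region_id=region.region_id, k=k, centroids=centroids, seed=seed)


def assign_cluster(encoded: np.ndarray, model: ClusterModel) -> np.ndarray:
    """Nearest centroid by Euclidean distance; ties go to the lowest cluster id."""
    d2 = ((encoded[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)  # argmin takes the first (lowest id) on ties


class _TanhMLP:
    """Fully connected tanh network trained by full-batch Adam on weighted MSE."""

    def __init__(self, widths: Sequence[int], rng: np.random.Generator):
        self.widths = tuple(widths)
        self.W = [
            rng.normal(0.0, 1.0 / np.sqrt(widths[i]), size=(widths[i], widths[i + 1]))
            for i in range(len(widths) - 1)
        ]
        self.b = [np.zeros(widths[i + 1]) for i in range(len(widths) - 1)]

    def forward(self, X: np.ndarray) -> list[np.ndarray]:
        acts = [X]
        for W, b in zip(self.W, self.b):
            acts.append(np.tanh(acts[-1] @ W + b))
        return acts

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[-1]

    def per_sample_loss(self, X: np.ndarray) -> np.ndarray:
        return ((self.reconstruct(X) - X) ** 2).mean(axis=1)

    def fit(self, X: np.ndarray, w: np.ndarray, params: AutoencoderParams) -> list[float]:
        wn = w / w.sum()
        n_out = X.shape[1]
        # Anchor the resting output at the weighted data mean.  A tanh network
        # with zero biases is an odd function, so it would reconstruct the
        # bitwise complement of its training archetype as well as the
        # archetype itself; seeding the output bias with atanh(mean) breaks
        # that symmetry and leaves the bottleneck to encode only the variance
        # around the archetype.
        mean = np.clip(wn @ X, -0.98, 0.98)
        self.b[-1] = np.arctanh(mean)
        m = [np.zeros_like(W) for W in self.W] + [np.zeros_like(b) for b in self.b]
        v = [np.zeros_like(g) for g in m]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        history: list[float] = []
        best = np.inf
        stale = 0
        for t in range(1, params.epochs + 1):
            acts = self.forward(X)
            out = acts[-1]
            loss = float((wn * ((out - X) ** 2).mean(axis=1)).sum())
            history.append(loss)
            if not np.isfinite(loss):
                raise ValidationError(
                    f"autoencoder training diverged at epoch {t} (loss={loss})"
                )
            # backprop; objective = sum_i wn_i * mean_j (out_ij - x_ij)^2
            delta = (2.0 / n_out) * (out - X) * wn[:, None] * (1.0 - out**2)
            grads_W = []
            grads_b = []
            for layer in range(len(self.W) - 1, -1, -1):
                grads_W.append(acts[layer].T @ delta)
                grads_b.append(delta.sum(axis=0))
                if layer > 0:
                    delta = (delta @ self.W[layer].T) * (1.0 - acts[layer] ** 2)
            grads = list(reversed(grads_W)) + list(reversed(grads_b))
            tensors = self.W + self.b
            for i, (g, p) in enumerate(zip(grads, tensors)):
                m[i] = beta1 * m[i] + (1 - beta1) * g
                v[i] = beta2 * v[i] + (1 - beta2) * g**2
                mhat = m[i] / (1 - beta1**t)
                vhat = v[i] / (1 - beta2**t)
                p -= params.learning_rate * mhat / (np.sqrt(vhat) + eps)
            if loss < best * (1.0 - params.plateau_tol):
                best = loss
                stale = 0
            else:
                stale += 1
                if stale >= params.plateau_patience:
                    break
        return history


@dataclass
class AutoencoderModel:
    """One trained autoencoder with its abnormal-read loss threshold."""

    region_id: str
    cluster_id: int | str  # cluster index, or "all" for the k=1 variant
    net: _TanhMLP
    loss_threshold: float
    params: AutoencoderParams

    def losses(self, encoded: np.ndarray) -> np.ndarray:
        return self.net.per_sample_loss(encoded)

    def is_abnormal(self, encoded: np.ndarray) -> np.ndarray:
        return self.losses(encoded) > self.loss_threshold


def train_autoencoder(
    cluster_reads: Sequence[ReadPattern],
    region: AmpliconRegion,
    params: AutoencoderParams | None = None,
    cluster_id: int | str = "all",
) -> AutoencoderModel:
    """Train one autoencoder on the (count-weighted) reads of a cluster.

    The loss threshold is the count-weighted 99th percentile of training-read
    reconstruction losses, so at most ~1% of training reads exceed it.
    """
    params = params or AutoencoderParams()
    if not cluster_reads:
        raise ValidationError(f"region {region.region_id!r}: empty autoencoder training set")
    X, w = encode_reads(cluster_reads)
    if X.shape[1] != region.n_cpgs:
        raise ValidationError(
            f"pattern width {X.shape[1]} != {region.n_cpgs} CpGs of region {region.region_id!r}"
        )
    widths = (region.n_cpgs, *params.hidden, region.n_cpgs)
    rng = np.random.default_rng(params.seed)
    net = _TanhMLP(widths, rng)
    net.fit(X, w, params)
    losses = net.per_sample_loss(X)
    threshold = weighted_percentile(losses, w.astype(int), 99.0)
    return AutoencoderModel(
        region_id=region.region_id,
        cluster_id=cluster_id,
        net=net,
        loss_threshold=float(threshold),
        params=params,
    )


@dataclass
class RegionAutoencoders:
    """Cluster router plus per-cluster autoencoders for one region."""

    region_id: str
    cluster_model: ClusterModel
    models: dict[int, AutoencoderModel]

    def classify_reads(self, reads: Sequence[ReadPattern]) -> tuple[np.ndarray, np.ndarray]:
        """Per collapsed pattern: abnormal flag and count weight."""
        X, w = encode_reads(reads)
        assignments = assign_cluster(X, self.cluster_model)
        abnormal = np.zeros(len(reads), dtype=bool)
        for cid, model in self.models.items():
            mask = assignments == cid
            if mask.any():
                abnormal[mask] = model.is_abnormal(X[mask])
        return abnormal, w

    def anomaly_ratio(self, reads: Sequence[ReadPattern]) -> float | None:
        if not reads:
            return None
        abnormal, w = self.classify_reads(reads)
        return float(w[abnormal].sum() / w.sum())


def _train_region(
    train_reads: Sequence[ReadPattern],
    region: AmpliconRegion,
    n_clusters: int,
    params: AutoencoderParams,
) -> RegionAutoencoders:
    k = max(int(n_clusters), 1)  # k <= 1 (or 0 = "no clustering") collapses to one cluster
    cluster_model = fit_clusters(train_reads, region, k=k, seed=params.seed)
    X, _ = encode_reads(train_reads)
    assignments = assign_cluster(X, cluster_model)
    models: dict[int, AutoencoderModel] = {}
    for cid in range(cluster_model.k):
        sub = [p for p, a in zip(train_reads, assignments) if a == cid]
        if not sub:
            logger.warning("region %s: cluster %d is empty, dropped", region.region_id, cid)
            continue
        sub_params = AutoencoderParams(
            hidden=params.hidden,
            epochs=params.epochs,
            learning_rate=params.learning_rate,
            plateau_tol=params.plateau_tol,
            plateau_patience=params.plateau_patience,
            seed=params.seed + cid,
        )
        models[cid] = train_autoencoder(sub, region, sub_params, cluster_id=cid)
    return RegionAutoencoders(region.region_id, cluster_model, models)


@dataclass
class PanelAutoencoder:
    """Autoencoder anomaly detector over a full panel.

    Trained on control reads only (no AML training set required); with
    ``n_clusters=5`` this is the clustered variant, with ``n_clusters<=1``
    the plain one.
    """

    panel: RegionPanel
    regions: dict[str, RegionAutoencoders]
    n_clusters: int
    cutoff: float = float("nan")

    @classmethod
    def train(
        cls,
        control_train: Sequence[SampleReads],
        panel: RegionPanel,
        n_clusters: int = 5,
        params: AutoencoderParams | None = None,
    ) -> "PanelAutoencoder":
        params = params or AutoencoderParams()
        regions = {}
        for region in panel:
            pooled = [p for s in control_train for p in s.patterns.get(region.region_id, [])]
            regions[region.region_id] = _train_region(pooled, region, n_clusters, params)
        pa = cls(panel=panel, regions=regions, n_clusters=max(int(n_clusters), 1))
        train_scores = [pa.classify(s).score for s in control_train]
        pa.cutoff = calibrate_anomaly_cutoff(train_scores)
        return pa

    def classify(self, sample: SampleReads) -> AnomalyResult:
        ratios = {
            region.region_id: self.regions[region.region_id].anomaly_ratio(
                sample.patterns.get(region.region_id, [])
            )
            for region in self.panel
        }
        cutoff = 0.0 if np.isnan(self.cutoff) else self.cutoff
        method = "ae_cluster" if self.n_clusters > 1 else "ae"
        return build_result(sample.sample_id, ratios, cutoff, method=method)
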