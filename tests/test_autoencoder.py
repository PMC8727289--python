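"""±1 encoding, K-means routing, autoencoder training and read classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epimrd import (
    AutoencoderParams,
    CloneProfile,
    PanelAutoencoder,
    ReadPattern,
    ValidationError,
    assign_cluster,
    encode_reads,
    fit_clusters,
    simulate_sample,
    train_autoencoder,
)
from epimrd._stats import weighted_percentile


def patterns(region_id, rows, sample_id="s"):
    return [ReadPattern(sample_id, region_id, bits, count) for bits, count in rows]


class TestEncoding:
    def test_plus_minus_one_convention(self):
        X, w = encode_reads(patterns("toy", [((0, 1, 0, 1), 2)]))
        assert X.tolist() == [[-1.0, 1.0, -1.0, 1.0]]
        assert w.tolist() == [2.0]

    def test_all_zero_pattern(self):
        X, _ = encode_reads(patterns("toy", [((0, 0, 0, 0), 1)]))
        assert (X == -1).all()

    @settings(derandomize=True, max_examples=50)
    @given(bits=st.lists(st.integers(0, 1), min_size=1, max_size=15))
    def test_sign_decode_round_trip(self, bits):
        X, _ = encode_reads(patterns("toy", [(tuple(bits), 1)]))
        assert ((X > 0).astype(int)[0] == np.array(bits)).all()


class TestClustering:
    def test_two_pure_populations(self, toy_region):
        reads = patterns("toy", [((0, 0, 0, 0), 100), ((1, 1, 1, 1), 100)])
        cm = fit_clusters(reads, toy_region, k=2, seed=0)
        got = {tuple(c) for c in cm.centroids}
        assert got == {(-1.0, -1.0, -1.0, -1.0), (1.0, 1.0, 1.0, 1.0)}

    def test_planted_populations_map_to_distinct_clusters(self, panel):
        """Five well-separated pattern populations with 1% bit noise occupy
        five distinct clusters."""
        region = panel.region("cg22797031")  # 10 CpGs
        rng = np.random.default_rng(0)
        archetypes = np.array(
            [
                [0] * 10,
                [1] * 10,
                [1] * 5 + [0] * 5,
                [0] * 5 + [1] * 5,
                [1, 0] * 5,
            ]
        )
        reads = []
        truth = []
        for label, arch in enumerate(archetypes):
            for _ in range(200):
                bits = np.where(rng.uniform(size=10) < 0.01, 1 - arch, arch)
                reads.append(ReadPattern("s", region.region_id, tuple(int(b) for b in bits)))
                truth.append(label)
        cm = fit_clusters(reads, region, k=5, seed=0)
        X, _ = encode_reads(reads)
        assigned = assign_cluster(X, cm)
        mapping = {}
        for label in range(5):
            ids = set(assigned[np.array(truth) == label])
            assert len(ids) == 1  # population is not split
            mapping[label] = ids.pop()
        assert len(set(mapping.values())) == 5  # populations not merged

    def test_k_reduced_for_single_pattern(self, toy_region, caplog):
        reads = patterns("toy", [((0, 0, 0, 0), 1)])
        with caplog.at_level("WARNING"):
            cm = fit_clusters(reads, toy_region, k=5, seed=0)
        assert cm.k == 1
        assert cm.centroids.tolist() == [[-1.0, -1.0, -1.0, -1.0]]

    def test_empty_training_set_rejected(self, toy_region):
        with pytest.raises(ValidationError):
            fit_clusters([], toy_region)

    def test_tie_goes_to_lowest_cluster_id(self, toy_region):
        cm = fit_clusters(
            patterns("toy", [((0, 0, 0, 0), 10), ((1, 1, 1, 1), 10)]), toy_region, k=2, seed=0
        )
        # the midpoint is equidistant from both centroids
        mid = np.zeros((1, 4))
        assert assign_cluster(mid, cm)[0] == 0


class TestAutoencoderTraining:
    def test_homogeneous_cluster_reconstructs(self, toy_region):
        """A single repeated pattern is reconstructed nearly perfectly."""
        reads = patterns("toy", [((0, 0, 0, 0), 1000)])
        model = train_autoencoder(reads, toy_region, AutoencoderParams(seed=0))
        X, _ = encode_reads(reads)
        assert float(np.median(model.losses(X))) < 0.01

    def test_at_most_one_percent_of_training_reads_flagged(self, toy_region):
        rng = np.random.default_rng(1)
        rows = [(tuple(int(b) for b in (rng.uniform(size=4) < 0.05)), 1) for _ in range(500)]
        model = train_autoencoder(patterns("toy", rows), toy_region, AutoencoderParams(seed=1))
        X, w = encode_reads(patterns("toy", rows))
        flagged = w[model.is_abnormal(X)].sum() / w.sum()
        assert flagged <= 0.01 + 1.0 / w.sum()

    def test_deterministic_under_seed(self, toy_region):
        reads = patterns("toy", [((0, 0, 0, 0), 50), ((0, 1, 0, 0), 5)])
        t1 = train_autoencoder(reads, toy_region, AutoencoderParams(seed=2)).loss_threshold
        t2 = train_autoencoder(reads, toy_region, AutoencoderParams(seed=2)).loss_threshold
        assert t1 == t2

    def test_complement_of_training_archetype_flagged(self, toy_region):
        """Training on all-unmethylated reads: the all-methylated read is an
        out-of-distribution vector with loss far above threshold."""
        reads = patterns("toy", [((0, 0, 0, 0), 1000)])
        model = train_autoencoder(reads, toy_region, AutoencoderParams(seed=0))
        comp, _ = encode_reads(patterns("toy", [((1, 1, 1, 1), 1)]))
        assert model.is_abnormal(comp)[0]

    def test_empty_training_set_rejected(self, toy_region):
        with pytest.raises(ValidationError):
            train_autoencoder([], toy_region)


class TestWeightedThreshold:
    @settings(derandomize=True, max_examples=50)
    @given(
        data=st.lists(
            st.tuples(st.floats(0, 10), st.integers(1, 20)), min_size=1, max_size=30
        ),
        q=st.floats(0, 100),
    )
    def test_matches_expansion_oracle(self, data, q):
        values = np.array([v for v, _ in data])
        counts = np.array([c for _, c in data])
        expected = np.percentile(np.repeat(values, counts), q)
        assert weighted_percentile(values, counts, q) == pytest.approx(expected, abs=1e-9)


class TestPanelVariants:
    def test_no_clustering_equals_k1(self, panel):
        """The plain autoencoder is the k=1 special case of the clustered one."""
        healthy = CloneProfile.healthy(panel)
        controls = [
            simulate_sample(healthy, panel, 300, seed=s, sample_id=f"c{s}") for s in range(6)
        ]
        params = AutoencoderParams(seed=4, epochs=200)
        plain = PanelAutoencoder.train(controls, panel, n_clusters=0, params=params)
        k1 = PanelAutoencoder.train(controls, panel, n_clusters=1, params=params)
        assert plain.cutoff == k1.cutoff
        probe = simulate_sample(healthy, panel, 300, seed=99, sample_id="probe")
        assert plain.classify(probe).ratios == k1.classify(probe).ratios

    def test_aberrant_sample_scores_above_control_band(self, panel):
        healthy = CloneProfile.healthy(panel)
        aberrant = CloneProfile.aberrant(panel)
        controls = [
            simulate_sample(healthy, panel, 300, seed=s, sample_id=f"c{s}") for s in range(8)
        ]
        ae = PanelAutoencoder.train(controls, panel, n_clusters=5,
                                    params=AutoencoderParams(seed=4, epochs=200))
        bad = simulate_sample(aberrant, panel, 300, seed=50, sample_id="aml")
        assert ae.classify(bad).score > 0.5
        assert ae.classify(bad).call == "positive"
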