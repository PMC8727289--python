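"""Candidate-CpG selection: invariance filter, Δβ ranking, cross-study intersection."""

import numpy as np
import pandas as pd
import pytest

from epimrd import (
    BetaMatrix,
    CandidateSet,
    SelectionCriteria,
    filter_invariant_cpgs,
    intersect_candidates,
    rank_and_select,
    simulate_beta_matrix,
)


def control_matrix(rows: dict[str, list[float]]) -> BetaMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return BetaMatrix(df, {c: "control" for c in df.columns})


class TestInvariantFilter:
    def test_extreme_low_variance_cpg_kept(self):
        # mean 0.05, sample s.d. ~0.0082: extreme and stable
        m = control_matrix({"cg1": [0.04, 0.06, 0.05, 0.05]})
        assert filter_invariant_cpgs(m) == {"cg1"}

    def test_intermediate_mean_rejected(self):
        m = control_matrix({"cg1": [0.5, 0.5, 0.5, 0.5]})
        assert filter_invariant_cpgs(m) == set()

    def test_high_variance_rejected_despite_extreme_mean(self):
        # mean 0.92 > 0.9 but sample s.d. = 0.0808 > 0.05
        vals = [0.99, 0.85, 0.99, 0.85]
        assert np.std(vals, ddof=1) > 0.05
        m = control_matrix({"cg1": vals})
        assert filter_invariant_cpgs(m) == set()

    def test_too_few_observations_excluded_not_raised(self):
        m = control_matrix({"cg1": [0.05, np.nan, np.nan, np.nan]})
        assert filter_invariant_cpgs(m) == set()

    def test_agrees_with_brute_force_oracle(self):
        """Filter decisions match an independent per-CpG loop on a 500-CpG matrix."""
        matrix, _ = simulate_beta_matrix(seed=7)
        controls = matrix.restrict("control")
        crit = SelectionCriteria()
        got = filter_invariant_cpgs(controls, crit)
        expected = set()
        for cpg in controls.cpg_ids:
            vals = [v for v in controls.values.loc[cpg] if not np.isnan(v)]
            if len(vals) < 2:
                continue
            mean = sum(vals) / len(vals)
            sd = (sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
            if (mean < crit.low_bound or mean > crit.high_bound) and sd < crit.sd_max:
                expected.add(cpg)
        assert got == expected


def two_group_matrix(ctrl: dict[str, float], aml: dict[str, float], n=4) -> BetaMatrix:
    cpgs = list(ctrl)
    data = {f"c{i}": [ctrl[c] for c in cpgs] for i in range(n)}
    data.update({f"a{i}": [aml[c] for c in cpgs] for i in range(n)})
    df = pd.DataFrame(data, index=cpgs)
    groups = {s: ("control" if s.startswith("c") else "aml") for s in df.columns}
    return BetaMatrix(df, groups)


class TestRankAndSelect:
    def test_direction_split_and_truncation(self):
        m = two_group_matrix(
            {"cgA": 0.1, "cgB": 0.1, "cgC": 0.9}, {"cgA": 0.7, "cgB": 0.3, "cgC": 0.4}
        )
        cs = rank_and_select(m, {"cgA", "cgB", "cgC"}, SelectionCriteria(top_k=2))
        assert cs.hyper == ["cgA", "cgB"]  # deltas +0.6, +0.2
        assert cs.hypo == ["cgC"]  # delta -0.5
        assert cs.delta["cgC"] == pytest.approx(-0.5)

    def test_ties_broken_lexicographically(self):
        m = two_group_matrix({"cgB": 0.1, "cgA": 0.1}, {"cgB": 0.5, "cgA": 0.5})
        cs = rank_and_select(m, {"cgA", "cgB"})
        assert cs.hyper == ["cgA", "cgB"]

    def test_empty_eligible_set_warns_and_returns_empty(self, caplog):
        m = two_group_matrix({"cgA": 0.1}, {"cgA": 0.7})
        with caplog.at_level("WARNING"):
            cs = rank_and_select(m, set())
        assert cs.hyper == [] and cs.hypo == []

    def test_planted_cpgs_recovered(self):
        matrix, planted = simulate_beta_matrix(
            n_planted_hyper=20, n_planted_hypo=0, seed=3
        )
        eligible = filter_invariant_cpgs(matrix.restrict("control"))
        cs = rank_and_select(matrix, eligible)
        assert set(planted) <= set(cs.hyper)


class TestIntersect:
    def _sets(self, *hypers):
        return [
            CandidateSet(hyper=list(h), delta={c: 0.5 for c in h}) for h in hypers
        ]

    def test_intersection_of_three(self):
        got = intersect_candidates(self._sets("abc", "bcd", "cb"))
        assert set(got.hyper) == {"b", "c"}

    def test_disjoint_lists_empty(self):
        got = intersect_candidates(self._sets("ab", "cd"))
        assert got.hyper == []

    def test_order_invariant(self):
        sets = self._sets("abc", "bcd", "cb")
        a = intersect_candidates(sets)
        b = intersect_candidates(sets[::-1])
        assert a.hyper == b.hyper and a.hypo == b.hypo

    def test_ordered_by_mean_abs_delta(self):
        s1 = CandidateSet(hyper=["x", "y"], delta={"x": 0.2, "y": 0.6})
        s2 = CandidateSet(hyper=["x", "y"], delta={"x": 0.3, "y": 0.7})
        got = intersect_candidates([s1, s2])
        assert got.hyper == ["y", "x"]

    def test_replication_across_synthetic_pairs(self):
        """A CpG planted in all three study pairs survives; one planted in
        only two of three does not."""
        sets = []
        for seed in (11, 12, 13):
            matrix, planted = simulate_beta_matrix(
                n_planted_hyper=5, n_planted_hypo=5, seed=seed
            )
            eligible = filter_invariant_cpgs(matrix.restrict("control"))
            sets.append(rank_and_select(matrix, eligible))
        always = intersect_candidates(sets)
        # planted ids are deterministic (same positions each seed)
        assert set(planted) <= set(always.hyper) | set(always.hypo)
        # drop one planted CpG from one pair only
        pruned = CandidateSet(
            hyper=[c for c in sets[0].hyper if c != planted[0]],
            hypo=sets[0].hypo,
            delta=sets[0].delta,
        )
        partial = intersect_candidates([pruned, sets[1], sets[2]])
        assert planted[0] not in partial.hyper
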