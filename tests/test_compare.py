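"""Permutation network comparison: S, M, post-hoc tests."""

import itertools

import numpy as np
import pytest

import inflanet as inf
from inflanet.compare import CompareError, _gs
from inflanet.estimate import EstimatorSettings, _weights_fast

FAST = EstimatorSettings(n_lambda=40, min_ratio=0.05)


def _cohort(spec, n, seed, arm_index=0):
    m = [inf.MarginalSpec("skewed_continuous")] * spec.n_vars
    return inf.sample_cohort(spec, m, n, seed=seed, arm_index=arm_index)


class TestSStatistic:
    def test_printed_group_strengths(self):
        assert inf.s_from_global_strengths(5.79, 4.48) == pytest.approx(1.31)
        assert inf.s_from_global_strengths(6.16, 5.79) == pytest.approx(0.37)


class TestNct:
    def test_identical_groups_yield_null_result(self):
        spec = inf.build_true_network("hub", 5, -0.3)
        a = _cohort(spec, 80, seed=1)
        res = inf.nct(a, a, n_permutations=100, settings=FAST, seed=2)
        assert res.S_observed == 0.0
        assert res.M_observed == 0.0
        assert res.p_S == 1.0 and res.p_M == 1.0

    def test_variable_mismatch_rejected(self):
        spec = inf.build_true_network("hub", 4, -0.3)
        a = _cohort(spec, 50, seed=1)
        b = _cohort(spec, 50, seed=2)
        b = b.subset(columns=list(reversed(b.variables)))
        with pytest.raises(CompareError):
            inf.nct(a, b, 10, FAST)

    def test_arm_swap_symmetry(self):
        spec = inf.build_true_network("chain", 5, -0.4)
        a = _cohort(spec, 60, seed=3, arm_index=0)
        b = _cohort(spec, 70, seed=3, arm_index=1)
        r1 = inf.nct(a, b, 200, FAST, seed=4)
        r2 = inf.nct(b, a, 200, FAST, seed=4)
        assert r1.S_observed == r2.S_observed
        assert r1.M_observed == r2.M_observed
        assert r1.p_S == r2.p_S and r1.p_M == r2.p_M

    def test_paired_design_requires_aligned_sizes(self):
        spec = inf.build_true_network("chain", 3, -0.4)
        with pytest.raises(CompareError):
            inf.nct(_cohort(spec, 30, 1), _cohort(spec, 40, 2), 10, FAST, design="paired")

    def test_paired_design_runs_and_is_deterministic(self):
        spec = inf.build_true_network("chain", 4, -0.4)
        a = _cohort(spec, 60, seed=5, arm_index=0)
        b = _cohort(spec, 60, seed=5, arm_index=1)
        r1 = inf.nct(a, b, 100, FAST, design="paired", seed=6)
        r2 = inf.nct(a, b, 100, FAST, design="paired", seed=6)
        assert r1.p_S == r2.p_S
        assert np.array_equal(r1.null_S, r2.null_S)

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        # n=6/arm, p=3: every C(12,6) regrouping enumerated as the oracle
        spec = inf.build_true_network("chain", 3, -0.5)
        a = _cohort(spec, 6, seed=7, arm_index=0)
        b = _cohort(spec, 6, seed=7, arm_index=1)
        res = inf.nct(a, b, 2000, FAST, seed=8)
        pooled = np.vstack([a.matrix(), b.matrix()])
        iu = np.triu_indices(3, 1)
        stats = []
        for combo in itertools.combinations(range(12), 6):
            g1 = np.array(combo)
            g2 = np.array([i for i in range(12) if i not in combo])
            w1 = _weights_fast(pooled[g1], 6, FAST)
            w2 = _weights_fast(pooled[g2], 6, FAST)
            stats.append(abs(_gs(w1, iu) - _gs(w2, iu)))
        stats = np.array(stats)
        p_exact = float((stats >= res.S_observed - 1e-12).mean())
        assert res.p_S == pytest.approx(p_exact, abs=0.03)

    def test_add_one_pvalues_never_zero(self):
        spec = inf.build_true_network("hub", 4, -0.35)
        a = _cohort(spec, 50, seed=9, arm_index=0)
        b = _cohort(inf.build_true_network("empty", 4), 50, seed=9, arm_index=1)
        res = inf.nct(a, b, 50, FAST, seed=10)
        assert 0 < res.p_S <= 1 and 0 < res.p_M <= 1
        assert res.p_S >= 1 / 51


class TestPosthoc:
    def _significant_pair(self):
        net = inf.build_true_network("hub", 6, -0.3)
        a = _cohort(net, 400, seed=11, arm_index=0)
        b = _cohort(inf.synth.attenuate_network(net, 0.2), 400, seed=11, arm_index=1)
        return inf.nct(a, b, 200, FAST, seed=12)

    def test_identical_groups_all_p_one(self):
        spec = inf.build_true_network("hub", 4, -0.3)
        a = _cohort(spec, 60, seed=13)
        res = inf.nct(a, a, 100, FAST, seed=14)
        cent = inf.posthoc_strength_centrality(res)
        assert np.all(cent["p_value"] == 1.0)
        edges = inf.posthoc_edge_invariance(res)
        assert np.all(edges["p_value"] == 1.0)
        assert np.all(edges["p_adjusted"] == 1.0)

    def test_posthoc_reports_both_group_strengths(self):
        res = self._significant_pair()
        cent = inf.posthoc_strength_centrality(res)
        assert {"strength_a", "strength_b", "abs_difference", "p_value"} <= set(cent.columns)
        s_a = np.abs(res.weights_a).sum(axis=1)
        assert np.allclose(cent["strength_a"], s_a)

    def test_attenuated_hub_attracts_smallest_posthoc_p(self):
        hits = 0
        for rep in range(10):
            net = inf.build_true_network("hub", 6, -0.3)
            a = _cohort(net, 500, seed=100 + rep, arm_index=0)
            b = _cohort(inf.synth.attenuate_network(net, 0.3), 500, seed=100 + rep, arm_index=1)
            res = inf.nct(a, b, 200, FAST, seed=200 + rep)
            cent = inf.posthoc_strength_centrality(res)
            hits += cent["p_value"].idxmin() == "v01"
        assert hits >= 9

    def test_holm_adjustment_monotone(self):
        res = self._significant_pair()
        edges = inf.posthoc_edge_invariance(res, adjustment="holm")
        assert np.all(edges["p_adjusted"] >= edges["p_value"] - 1e-12)
        raw = inf.posthoc_edge_invariance(res, adjustment="none")
        assert np.allclose(raw["p_adjusted"], raw["p_value"])

    def test_edge_subset_selection(self):
        res = self._significant_pair()
        sub = inf.posthoc_edge_invariance(res, edges=[("v01", "v02")])
        assert len(sub) == 1
        with pytest.raises(CompareError):
            inf.posthoc_edge_invariance(res, edges=[("v01", "nope")])

    def test_requires_parent_result(self):
        with pytest.raises(CompareError):
            inf.posthoc_strength_centrality("not a result")
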