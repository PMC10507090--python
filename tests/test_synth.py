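"""Generator tests: planted networks, copula marginals, two-arm designs."""

import numpy as np
import pytest
from scipy import stats

import inflanet as inf
from inflanet.synth import (
    SynthError,
    attenuate_network,
    binary_from_rate,
    make_study_cohorts,
    partials_from_precision,
    skewed_from_mean_sd,
    study_true_network,
)


class TestBuildTrueNetwork:
    def test_empty_topology_is_identity(self):
        spec = inf.build_true_network("empty", 4)
        assert np.array_equal(spec.precision, np.eye(4))
        assert np.all(spec.true_partials == 0)

    def test_chain_partials_match_hand_formula(self):
        # precision [[1,-.5,0],[-.5,1,-.5],[0,-.5,1]]: partial(1,2) = +0.5
        spec = inf.build_true_network("chain", 3, -0.5)
        expected = np.array([[1, -0.5, 0], [-0.5, 1, -0.5], [0, -0.5, 1]])
        assert np.allclose(spec.precision, expected)
        assert np.linalg.eigvalsh(spec.precision)[0] > 0
        assert spec.true_partials[0, 1] == pytest.approx(0.5)
        assert spec.true_partials[0, 2] == 0.0

    def test_hub_degrees_and_strength(self):
        spec = inf.build_true_network("hub", 5, -0.3)
        nonzero = np.count_nonzero(spec.true_partials, axis=1)
        assert nonzero[0] == 4 and np.all(nonzero[1:] == 1)
        strengths = np.abs(spec.true_partials).sum(axis=1)
        assert np.all(strengths[0] > strengths[1:])

    def test_block_assignment_matches_pattern(self):
        spec = inf.build_true_network("block", 6, -0.2, n_blocks=2)
        assert list(spec.block_assignment) == [0, 0, 0, 1, 1, 1]
        assert spec.true_partials[0, 3] == 0.0
        assert spec.true_partials[0, 1] != 0.0

    def test_infeasible_edge_value_raises_with_magnitude(self):
        # hub(12) at -0.9 needs a shrink factor ~0.32; a floor of 0.5 makes
        # the requested magnitude infeasible and the error must name it
        with pytest.raises(SynthError, match="0.9"):
            inf.build_true_network("hub", 12, -0.9, shrink_floor=0.5)

    def test_pd_repair_never_inflates_partials(self):
        spec = inf.build_true_network("hub", 12, -0.31)  # needs a shrink
        assert spec.shrink_factor < 1.0
        raw = np.eye(12)
        raw[0, 1:] = raw[1:, 0] = -0.31
        assert np.all(
            np.abs(spec.true_partials) <= np.abs(partials_from_precision(raw)) + 1e-12
        )


class TestMarginals:
    def test_ordinal_thresholds_must_increase(self):
        with pytest.raises(SynthError):
            inf.MarginalSpec("ordinal", thresholds=(0.5, 0.1))

    def test_skewed_transform_is_monotone_and_skewed(self, rng):
        m = inf.MarginalSpec("skewed_continuous")
        z = np.sort(rng.standard_normal(1000))
        x = m.transform(z)
        assert np.all(np.diff(x) > 0)
        assert stats.skew(m.transform(rng.standard_normal(200_000))) > 1

    def test_calibrated_marginal_matches_mean_sd(self, rng):
        m = skewed_from_mean_sd(2.5, 0.64)
        x = m.transform(rng.standard_normal(500_000))
        assert x.mean() == pytest.approx(2.5, rel=0.01)
        assert x.std() == pytest.approx(0.64, rel=0.02)

    def test_binary_rate(self, rng):
        m = binary_from_rate(0.258)
        x = m.transform(rng.standard_normal(200_000))
        assert x.mean() == pytest.approx(0.258, abs=0.005)


class TestSampleCohort:
    def test_independence_gives_null_spearman(self):
        spec = inf.build_true_network("empty", 4)
        m = [inf.MarginalSpec("skewed_continuous")] * 4
        tbl = inf.sample_cohort(spec, m, 5000, seed=0)
        corr = inf.rank_correlation_matrix(tbl).matrix
        off = corr[np.triu_indices(4, 1)]
        assert np.all(np.abs(off) < 0.05)

    def test_spearman_of_bivariate_normal_closed_form(self):
        # population Spearman of a normal pair: (6/pi) asin(rho/2); monotone
        # marginals leave ranks unchanged
        rho = 0.5
        prec = np.linalg.inv(np.array([[1, rho], [rho, 1]]))
        spec = inf.TrueNetworkSpec.from_precision(prec)
        m = [
            inf.MarginalSpec("skewed_continuous"),
            inf.MarginalSpec("skewed_continuous", shape=2.0),
        ]
        tbl = inf.sample_cohort(spec, m, 50_000, seed=3)
        r = inf.rank_correlation_matrix(tbl).matrix[0, 1]
        assert r == pytest.approx(6 / np.pi * np.arcsin(rho / 2), abs=0.01)

    def test_ordinal_category_proportions_match_normal_cdf(self):
        spec = inf.build_true_network("empty", 2)
        m = [inf.MarginalSpec("ordinal", thresholds=(-1.0, 0.0, 1.0))] * 2
        tbl = inf.sample_cohort(spec, m, 50_000, seed=4)
        props = tbl.data.iloc[:, 0].value_counts(normalize=True).sort_index()
        expected = np.diff(stats.norm.cdf([-np.inf, -1, 0, 1, np.inf]))
        assert np.allclose(props.to_numpy(), expected, atol=0.01)

    def test_seed_determinism_byte_identical(self):
        spec = inf.build_true_network("chain", 3, -0.4)
        m = [inf.MarginalSpec("skewed_continuous")] * 3
        a = inf.sample_cohort(spec, m, 50, seed=9)
        b = inf.sample_cohort(spec, m, 50, seed=9)
        assert a.data.equals(b.data)
        c = inf.sample_cohort(spec, m, 50, seed=10)
        assert not a.data.equals(c.data)

    def test_rejects_tiny_samples(self):
        spec = inf.build_true_network("empty", 2)
        with pytest.raises(SynthError):
            inf.sample_cohort(spec, [inf.MarginalSpec("skewed_continuous")] * 2, 2, seed=0)


class TestTwoGroupCohort:
    def _spec(self, attenuation):
        net = inf.build_true_network("chain", 3, -0.5)
        return inf.CohortSpec(
            n_per_arm=(30, 30),
            network_A=net,
            attenuation=attenuation,
            marginals=[inf.MarginalSpec("skewed_continuous")] * 3,
            seed=5,
        )

    def test_attenuation_one_shares_precision(self):
        pair = inf.make_two_group_cohort(self._spec(1.0))
        assert np.array_equal(pair.network_a.precision, pair.network_b.precision)

    def test_attenuation_zero_empties_arm_b(self):
        pair = inf.make_two_group_cohort(self._spec(0.0))
        assert np.all(pair.network_b.true_partials == 0)
        assert pair.true_global_strengths[1] == 0.0

    def test_attenuation_half_scales_partials_exactly(self):
        # chain(3, -0.5) at attenuation 0.5: partial 0.5 -> 0.25, repair no-op
        net_b = attenuate_network(inf.build_true_network("chain", 3, -0.5), 0.5)
        assert net_b.true_partials[0, 1] == pytest.approx(0.25)
        assert net_b.shrink_factor == 1.0

    def test_arms_use_independent_substreams(self):
        pair = inf.make_two_group_cohort(self._spec(1.0))
        assert not pair.arm_a.data.iloc[:10].equals(pair.arm_b.data.iloc[:10])


class TestStudyCohorts:
    def test_study_tables_have_expected_shape_and_roles(self):
        study = make_study_cohorts((20, 20), seed=0)
        base = study.baseline
        assert base.n_subjects == 40
        assert len(base.names_with(role="cytokine")) == 12
        assert len(base.names_with(role="symptom")) == 23
        assert len(base.names_with(role="covariate")) == 3
        assert base.names_with(role="screening") == ["CRP_screen"]
        assert set(base.data["treatment"].unique()) == {1, 2}
        assert study.followup.n_subjects == 40

    def test_planted_network_is_well_conditioned(self):
        net = study_true_network()
        assert np.linalg.eigvalsh(net.precision)[0] > 1e-3
        # the pro-inflammatory trio forms the strongest true hub
        names, _, _, _ = __import__("inflanet.synth", fromlist=["study_variables"]).study_variables()
        strengths = np.abs(net.true_partials).sum(axis=1)
        cyto = strengths[:12]
        top3 = {names[i] for i in np.argsort(-cyto)[:3]}
        assert top3 == {"IL-6", "TNF-a", "IFN-g"}
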