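"""LA-AIDS estimation, elasticity formula and tax mechanics tests."""

import numpy as np
import pytest

import ssbtax as st
from ssbtax.demand import GOODS, DemandParameters, elasticities_from_params
from ssbtax.synthpop import generate_household_panel


class TestLAAIDSEstimation:
    def test_noiseless_identification(self, true_demand_params):
        panel = generate_household_panel(2000, true_demand_params, 0.0, seed=2)
        res = st.LAAIDS.from_dataframe(panel).fit()
        np.testing.assert_allclose(res.params.alpha, true_demand_params.alpha, atol=1e-8)
        np.testing.assert_allclose(res.params.beta, true_demand_params.beta, atol=1e-8)
        np.testing.assert_allclose(res.params.gamma, true_demand_params.gamma, atol=1e-8)

    @pytest.mark.parametrize("restrictions", ["none", "homogeneity", "homogeneity+symmetry"])
    def test_estimated_params_satisfy_adding_up(self, true_demand_params, restrictions):
        panel = generate_household_panel(3000, true_demand_params, 0.01, seed=6)
        params = st.estimate_laaids(panel, restrictions)
        assert abs(params.alpha.sum() - 1) < 1e-10
        assert abs(params.beta.sum()) < 1e-10
        assert np.abs(params.gamma.sum(axis=0)).max() < 1e-10
        if restrictions != "none":
            assert np.abs(params.gamma.sum(axis=1)).max() < 1e-10
        if restrictions == "homogeneity+symmetry":
            assert np.abs(params.gamma - params.gamma.T).max() < 1e-10

    def test_noisy_recovery_within_tolerance(self, true_demand_params):
        panel = generate_household_panel(5000, true_demand_params, 0.02, seed=3)
        res = st.LAAIDS.from_dataframe(panel).fit()
        truth = elasticities_from_params(true_demand_params, res.mean_shares)
        est = res.elasticities()
        assert np.abs(est.values - truth.values).max() < 0.05

    def test_collinear_prices_raise_named_error(self, true_demand_params):
        panel = generate_household_panel(500, true_demand_params, 0.01, seed=8)
        panel["p_juice"] = panel["p_ssb"]
        with pytest.raises(np.linalg.LinAlgError, match="ln p_"):
            st.LAAIDS.from_dataframe(panel).fit()

    def test_too_few_households_rejected(self, true_demand_params):
        panel = generate_household_panel(30, true_demand_params, 0.01, seed=8)
        with pytest.raises(ValueError, match="households"):
            st.estimate_laaids(panel)

    def test_summary_mentions_goods_and_elasticities(self, true_demand_params):
        panel = generate_household_panel(1000, true_demand_params, 0.01, seed=8)
        text = st.LAAIDS.from_dataframe(panel).fit().summary()
        assert "ssb" in text and "elasticities" in text


class TestElasticityFormula:
    def test_cobb_douglas_limit(self):
        params = DemandParameters(np.array([0.2, 0.3, 0.5]), np.zeros(3), np.zeros((3, 3)))
        E = elasticities_from_params(params, np.array([0.2, 0.3, 0.5]))
        np.testing.assert_allclose(E.values, -np.eye(3), atol=1e-12)

    def test_hand_computed_own_price_value(self):
        # gamma_11 = 0.01, beta_1 = 0.05, wbar = (0.2, 0.3, 0.5):
        # e_11 = -1 + 0.01/0.2 - 0.05*0.2/0.2 = -1.0
        gamma = np.zeros((3, 3))
        gamma[0, 0] = 0.01
        params = DemandParameters(np.array([0.2, 0.3, 0.5]),
                                  np.array([0.05, 0.0, -0.05]), gamma)
        E = elasticities_from_params(params, np.array([0.2, 0.3, 0.5]))
        assert E.values[0, 0] == pytest.approx(-1.0, abs=1e-12)

    def test_zero_parameter_covariance_zero_se(self):
        params = DemandParameters(np.array([0.2, 0.3, 0.5]), np.zeros(3),
                                  np.zeros((3, 3)), cov=np.zeros((15, 15)))
        E = elasticities_from_params(params, np.array([0.2, 0.3, 0.5]))
        assert (E.se == 0).all()

    def test_zero_share_rejected(self):
        params = DemandParameters(np.array([0.2, 0.3, 0.5]), np.zeros(3), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            elasticities_from_params(params, np.array([0.0, 0.5, 0.5]))

    def test_formula_matches_numerical_demand_derivative(self, true_demand_params):
        # Marshallian demand implied by the share equations:
        # q_i = w_i(p, x) * x / p_i; elasticity = dln q_i / dln p_j
        params = true_demand_params
        wbar = params.alpha  # evaluate at p = 1, x = 1 where shares = alpha
        E = elasticities_from_params(params, wbar)

        def quantity(lnp, i):
            w = (params.alpha + params.gamma @ lnp
                 + params.beta * (0.0 - wbar @ lnp))
            return w[i] * np.exp(0.0) / np.exp(lnp[i])

        h = 1e-6
        for i in range(3):
            for j in range(3):
                lp, lm = np.zeros(3), np.zeros(3)
                lp[j] += h
                lm[j] -= h
                num = (np.log(quantity(lp, i)) - np.log(quantity(lm, i))) / (2 * h)
                assert num == pytest.approx(E.values[i, j], rel=1e-4, abs=1e-6)


class TestTaxMechanics:
    @pytest.mark.parametrize("rate,pt,expected", [
        (0.20, 0.82, 0.164), (0.20, 1.00, 0.20), (0.0, 0.9, 0.0)])
    def test_consumer_price_change(self, rate, pt, expected):
        assert st.consumer_price_change(rate, pt) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            st.consumer_price_change(-0.1, 0.8)

    def test_own_price_response_arithmetic(self):
        # 300 ml at dp/p = 0.164 with e = -0.956: 300 * (1 - 0.1568) = 252.97
        E = st.default_elasticity_matrix().without_substitution()
        q = st.apply_demand_response(np.array([300.0, 0.0, 0.0]),
                                     np.array([0.164, 0.0, 0.0]), E)
        assert q[0] == pytest.approx(300 * (1 - 0.956 * 0.164), abs=1e-9)
        assert q[0] == pytest.approx(252.97, abs=0.01)

    def test_cross_price_substitution_arithmetic(self):
        # juice rises by e_cross * dp/p = 0.052 * 0.164 = 0.85%
        E = st.default_elasticity_matrix()
        q = st.apply_demand_response(np.array([0.0, 200.0, 0.0]),
                                     np.array([0.164, 0.0, 0.0]), E)
        assert q[1] == pytest.approx(200 * (1 + 0.052 * 0.164), abs=1e-9)
        assert q[1] == pytest.approx(201.71, abs=0.01)

    def test_zero_price_change_is_identity(self):
        E = st.default_elasticity_matrix()
        q0 = np.array([120.0, 80.0, 50.0])
        np.testing.assert_array_equal(st.apply_demand_response(q0, np.zeros(3), E), q0)

    def test_floor_at_zero(self):
        E = st.ElasticityMatrix(-5.0 * np.eye(3))
        q = st.apply_demand_response(np.array([100.0, 0, 0]), np.array([0.5, 0, 0]), E)
        assert q[0] == 0.0

    def test_linearity_in_small_price_changes(self):
        E = st.default_elasticity_matrix()
        q0 = np.array([100.0, 100.0, 100.0])
        d1 = st.apply_demand_response(q0, np.array([0.01, 0, 0]), E) - q0
        d2 = st.apply_demand_response(q0, np.array([0, 0.01, 0]), E) - q0
        both = st.apply_demand_response(q0, np.array([0.01, 0.01, 0]), E) - q0
        np.testing.assert_allclose(both, d1 + d2, atol=1e-9)


class TestRecoveryBias:
    def test_mean_elasticity_bias_across_replicates(self, true_demand_params):
        """Over 20 replicate panels the recovery bias per elasticity < 0.02
        and estimates stay near the generating values."""
        errs = []
        for rep in range(20):
            panel = generate_household_panel(5000, true_demand_params, 0.02,
                                             seed=500 + rep)
            res = st.LAAIDS.from_dataframe(panel).fit()
            truth = elasticities_from_params(true_demand_params, res.mean_shares)
            errs.append(res.elasticities().values - truth.values)
        bias = np.mean(errs, axis=0)
        assert np.abs(bias).max() < 0.02
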