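import numpy as np
import pandas as pd
import pytest

from epispread import (COVARIATE_COLUMNS, SpreadParams, log_delta_r,
                       resection_covariate_scan, stepwise_regression,
                       virtual_resection_effect)
from epispread.experiments import make_regression_replicate


class TestVirtualResection:
    def test_isolating_resection_floors_ir(self, star5):
        params = SpreadParams(beta=0.5, gamma=0.5, T=5,
                              n_realizations=4000, rng_seed=0)
        oc = virtual_resection_effect(star5, [0], [1], params)
        assert oc.ir_resected == pytest.approx(1 / 5)
        assert oc.seed_isolated
        assert oc.delta_r == pytest.approx(1 - (1 / 5) / oc.ir_baseline)

    def test_empty_resection_is_zero_effect(self, star5):
        params = SpreadParams(beta=0.5, gamma=0.5, T=5,
                              n_realizations=500, rng_seed=1)
        oc = virtual_resection_effect(star5, [], [1], params)
        assert oc.delta_r == 0.0
        assert oc.ir_resected == oc.ir_baseline
        assert oc.covariates["S_RA"] == 0
        assert oc.covariates["E_RA"] == 0

    def test_covariate_keys_complete(self, star5):
        params = SpreadParams(beta=0.4, gamma=0.4, T=5,
                              n_realizations=200, rng_seed=2)
        oc = virtual_resection_effect(star5, [2], [1], params)
        assert set(oc.covariates) == set(COVARIATE_COLUMNS)
        assert oc.covariates["ratio"] == pytest.approx(
            0.4 * star5.mean_degree / 0.4)
        row = oc.row()
        assert {"IR_0", "IR_R", "delta_R"} <= set(row)

    def test_delta_covariates_are_decreases(self, small_edr):
        from epispread import threshold_network
        net, _ = small_edr
        thr = threshold_network(net.weights, 0.2)
        params = SpreadParams(beta=0.3, gamma=0.2, T=50,
                              n_realizations=300, rng_seed=3)
        oc = virtual_resection_effect(thr, [5, 6], [0], params)
        c = oc.covariates
        assert c["dE_seed"] == pytest.approx(c["E_seed_0"] - c["E_seed_R"])
        assert c["dF_net"] == pytest.approx(c["F_net_0"] - c["F_net_R"])
        # resection can only lose paths: efficiency never increases
        assert c["dF_net"] >= -1e-12


class TestLogDeltaR:
    def test_positive_passthrough(self):
        d = np.array([0.1, 0.5, 1.0])
        assert np.allclose(log_delta_r(d), np.log(d))

    def test_floors_nonpositive_with_warning(self):
        d = np.array([0.2, 0.0, -0.05])
        with pytest.warns(UserWarning):
            out = log_delta_r(d)
        assert out[0] == pytest.approx(np.log(0.2))
        assert out[1] == out[2] == pytest.approx(np.log(0.02))

    def test_all_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log_delta_r(np.array([0.0, -0.1]))


class TestCovariateScan:
    def _outcomes(self, delta, extra):
        df = pd.DataFrame({"delta_R": delta})
        for name, vals in extra.items():
            df[name] = vals
        return df

    def test_exact_log_linear_relation(self):
        rng = np.random.default_rng(0)
        x = rng.random(40) + 0.5
        delta = np.exp(2 * x)
        df = self._outcomes(delta, {"E_RA": x})
        scan = resection_covariate_scan(df)
        row = scan[scan["covariate"] == "E_RA"].iloc[0]
        assert row["r2"] == pytest.approx(1.0)
        assert row["sign"] == "+"
        assert row["p"] < 1e-10

    def test_sign_flips_with_direction(self):
        rng = np.random.default_rng(1)
        x = rng.random(40) + 0.5
        df = self._outcomes(np.exp(-x), {"S_RA": x})
        scan = resection_covariate_scan(df)
        assert scan[scan["covariate"] == "S_RA"].iloc[0]["sign"] == "-"

    def test_constant_covariate_skipped(self):
        df = self._outcomes(np.array([0.1, 0.2, 0.3, 0.4]),
                            {"S_seed": np.ones(4), "E_RA": [1, 2, 3, 4]})
        scan = resection_covariate_scan(df)
        skipped = scan[scan["covariate"] == "S_seed"].iloc[0]
        assert np.isnan(skipped["r2"]) and "skipped" in skipped["note"]
        assert np.isfinite(scan[scan["covariate"] == "E_RA"].iloc[0]["r2"])


class TestStepwise:
    def test_recovers_generative_term(self):
        rng = np.random.default_rng(10)
        y, X = make_regression_replicate(n_obs=200, noise_scale=0.3, rng=rng)
        res = stepwise_regression(y, X)
        assert "generative" in res.selected
        assert res.r2 > 0.8
        assert res.f_pvalue < 1e-10

    def test_pure_noise_usually_empty(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=100)
        X = pd.DataFrame({"a": rng.normal(size=100),
                          "b": rng.normal(size=100)})
        res = stepwise_regression(y, X)
        assert res.r2 == 0.0 or len(res.selected) <= 1

    def test_collinear_column_dropped_with_warning(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=80)
        y = x + rng.normal(scale=0.2, size=80)
        X = pd.DataFrame({"x1": x, "x2": 2 * x})  # x2 is collinear with x1
        with pytest.warns(UserWarning, match="collinear"):
            res = stepwise_regression(y, X)
        assert res.dropped_collinear == ["x2"]
        assert res.selected == ["x1"]

    def test_column_order_invariant(self):
        rng = np.random.default_rng(13)
        y, X = make_regression_replicate(n_obs=120, noise_scale=0.5, rng=rng)
        res_a = stepwise_regression(y, X)
        res_b = stepwise_regression(y, X[list(X.columns)[::-1]])
        assert res_a.selected == res_b.selected
        assert res_a.r2 == pytest.approx(res_b.r2)

    def test_added_variable_data_present(self):
        rng = np.random.default_rng(14)
        y, X = make_regression_replicate(n_obs=150, noise_scale=0.4, rng=rng)
        res = stepwise_regression(y, X)
        for term in res.selected:
            av = res.added_variable_data[term]
            assert set(av.columns) == {"adjusted_x", "adjusted_y"}
            assert len(av) == 150
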