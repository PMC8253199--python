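"""Panel Granger machinery: within transformation, pooled OLS against
independent linear-algebra oracles, HPJ arithmetic, and test invariances."""

import dataclasses

import numpy as np
import pytest

from grangernet.granger import (GrangerPairResult, PairwiseError,
                                SingularDesignError, granger_test,
                                hpj_estimate, pairwise_matrix,
                                pooled_within_ols, within_demean)
from grangernet.panel import PanelDataset
from grangernet.synthetic import SyntheticSpec, simulate_panel_var


def dummy_ols_oracle(y, x, p):
    """Stacked OLS with one explicit intercept dummy per subject."""
    n, t_len = y.shape
    rows_y, rows_x, rows_d = [], [], []
    for i in range(n):
        for t in range(p, t_len):
            rows_y.append(y[i, t])
            rows_x.append([y[i, t - l] for l in range(1, p + 1)]
                          + [x[i, t - l] for l in range(1, p + 1)])
            d = np.zeros(n)
            d[i] = 1.0
            rows_d.append(d)
    X = np.hstack([np.asarray(rows_x), np.asarray(rows_d)])
    beta, *_ = np.linalg.lstsq(X, np.asarray(rows_y), rcond=None)
    return beta[: 2 * p]


class TestWithinDemean:
    def test_arithmetic(self):
        out = within_demean([np.array([1.0, 2.0, 3.0])])
        assert np.allclose(out[0], [-1, 0, 1])

    def test_idempotent_and_removes_offsets(self):
        g1 = np.array([5.0, 6.0, 7.0])
        g2 = np.array([-10.0, -12.0])
        out = within_demean([g1, g2])
        assert all(abs(g.mean()) < 1e-14 for g in out)
        again = within_demean(out)
        assert all(np.allclose(a, b) for a, b in zip(out, again))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            within_demean([np.array([])])


class TestPooledWithinOls:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(0)
        n, t_len = 6, 9
        x = rng.normal(size=(n, t_len))
        y = np.zeros((n, t_len))
        alpha = rng.normal(size=n)
        y[:, 0] = rng.normal(size=n)
        for t in range(1, t_len):
            y[:, t] = alpha + 0.5 * y[:, t - 1] + 0.3 * x[:, t - 1]
        theta, *_ = pooled_within_ols(y, x, p=1)
        assert theta[0] == pytest.approx(0.5, rel=1e-7)
        assert theta[1] == pytest.approx(0.3, rel=1e-7)

    def test_zero_cause_is_singular(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(4, 8))
        with pytest.raises(SingularDesignError, match="cause"):
            pooled_within_ols(y, np.zeros_like(y), p=1)

    @pytest.mark.parametrize("p", [1, 2])
    def test_matches_dummy_variable_oracle(self, p):
        # within estimator == explicit per-subject-intercept regression
        rng = np.random.default_rng(2)
        for _ in range(10):
            y = rng.normal(size=(5, 10))
            x = rng.normal(size=(5, 10))
            theta, *_ = pooled_within_ols(y, x, p=p)
            oracle = dummy_ols_oracle(y, x, p)
            assert np.allclose(theta, oracle, rtol=1e-10)

    def test_half_window_demeans_within_window(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(5, 9))
        x = rng.normal(size=(5, 9))
        theta_half, *_ = pooled_within_ols(y, x, p=1, time_window=(1, 5))
        oracle = dummy_ols_oracle(y[:, :5], x[:, :5], 1)
        assert np.allclose(theta_half, oracle, rtol=1e-10)


class TestHpjEstimate:
    def test_fixed_point_and_arithmetic(self):
        c = np.array([0.4, -0.2])
        assert np.allclose(hpj_estimate(c, c, c), c)
        out = hpj_estimate(np.array([1.0]), np.array([0.8]), np.array([0.6]))
        assert out == pytest.approx(1.3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            hpj_estimate(np.ones(2), np.ones(3), np.ones(2))

    def test_nickell_bias_reduction_own_lag(self):
        # the within estimate of rho=0.5 is biased down at T=10; HPJ
        # removes most of it (cross-lag bias is checked in acceptance)
        wr, hr = [], []
        for r in range(120):
            A = np.zeros((1, 2, 2))
            A[0, 1, 1], A[0, 0, 0] = 0.5, 0.3
            panel, _ = simulate_panel_var(SyntheticSpec(N=20, T=10, A=A, seed=r))
            res = granger_test(panel, "x0", "x1", p=1)
            wr.append(res.theta_within[0])
            hr.append(res.theta_hpj[0])
        assert abs(np.mean(hr) - 0.5) < abs(np.mean(wr) - 0.5)
        assert abs(np.mean(wr) - 0.5) > 0.1   # the bias HPJ is correcting


class TestGrangerTest:
    def test_cause_equals_effect_rejected(self, small_panel):
        with pytest.raises(ValueError, match="differ"):
            granger_test(small_panel, "x", "x")

    def test_too_short_panel_rejected(self):
        rng = np.random.default_rng(0)
        panel = PanelDataset(("A", "B", "C"), ("x", "y"),
                             rng.normal(size=(3, 4, 2)))
        with pytest.raises(ValueError, match="too small"):
            granger_test(panel, "x", "y", p=1)

    def test_scale_equivariance(self, study_shaped_panel):
        r1 = granger_test(study_shaped_panel, "v0", "v1")
        scaled = study_shaped_panel.values.copy()
        scaled[:, :, 0] *= 1000.0
        scaled[:, :, 1] *= 0.001
        r2 = granger_test(
            dataclasses.replace(study_shaped_panel, values=scaled), "v0", "v1")
        assert r1.wald == pytest.approx(r2.wald, rel=1e-8)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-8)

    def test_bootstrap_deterministic_given_seed(self, study_shaped_panel):
        r1 = granger_test(study_shaped_panel, "v0", "v1",
                          variance_mode="bootstrap", n_boot=99, seed=11)
        r2 = granger_test(study_shaped_panel, "v0", "v1",
                          variance_mode="bootstrap", n_boot=99, seed=11)
        assert r1.p_value == r2.p_value
        assert r1.variance_mode == "bootstrap"

    def test_bootstrap_and_clustered_agree_under_null(self):
        agree = 0
        reps = 20
        for r in range(reps):
            A = np.zeros((1, 2, 2))
            A[0, 0, 0] = A[0, 1, 1] = 0.3
            panel, _ = simulate_panel_var(SyntheticSpec(N=50, T=9, A=A, seed=r))
            rc = granger_test(panel, "x0", "x1", variance_mode="clustered")
            rb = granger_test(panel, "x0", "x1", variance_mode="bootstrap",
                              n_boot=199, seed=r)
            agree += (rc.p_value < 0.05) == (rb.p_value < 0.05)
        assert agree >= 18   # >= 90% agreement on the rejection decision

    def test_result_invariants(self):
        # p=2 needs T large enough for both half-windows to identify 4
        # coefficients plus fixed effects
        rng = np.random.default_rng(12)
        panel = PanelDataset(tuple(f"S{i}" for i in range(6)),
                             ("v2", "v5"), rng.normal(size=(6, 14, 2)))
        res = granger_test(panel, "v2", "v5", p=2)
        assert res.wald >= 0
        assert res.df == 2
        assert 0 <= res.p_value <= 1
        assert res.beta_hpj.shape == (2,)


class TestPairwiseMatrix:
    def test_counts(self, study_shaped_panel, small_panel):
        assert len(pairwise_matrix(study_shaped_panel)) == 56
        assert len(pairwise_matrix(small_panel)) == 2

    def test_permutation_invariance(self, study_shaped_panel):
        fwd = pairwise_matrix(study_shaped_panel,
                              variables=["v0", "v1", "v2"])
        rev = pairwise_matrix(study_shaped_panel,
                              variables=["v2", "v0", "v1"])
        as_set = lambda rs: {(r.cause, r.effect, round(r.p_value, 12))
                             for r in rs}
        assert as_set(fwd) == as_set(rev)

    def test_failures_collected_not_dropped(self, small_panel):
        vals = small_panel.values.copy()
        vals[:, :, 1] = 3.14   # constant variable: singular everywhere
        bad = dataclasses.replace(small_panel, values=vals)
        with pytest.raises(PairwiseError, match="2 pairwise"):
            pairwise_matrix(bad)
        results, failures = pairwise_matrix(bad, on_error="collect")
        assert results == [] and len(failures) == 2

    def test_single_variable_rejected(self, small_panel):
        with pytest.raises(ValueError, match="at least 2"):
            pairwise_matrix(small_panel, variables=["x"])
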