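"""Stage-1 model: likelihood fitting, BLUP oracles, shrinkage properties."""

import numpy as np
import pandas as pd
import pytest

from ehrlandmark.config import MARKERS
from ehrlandmark.mlmm import (
    MlmmParams,
    MlmmSpec,
    annual_visit_rate,
    blup,
    estimate_current_values,
    fit_mlmm_long,
)

from conftest import simulate_mlmm_data


def make_params(beta, G, sigma2, s=60.0, sex="male", **spec_kw) -> MlmmParams:
    """Assemble an MlmmParams object from known truth (no fitting)."""
    spec = MlmmSpec(s=s, sex=sex, **spec_kw)
    beta_dict = {}
    for m in MARKERS:
        b0, b1 = beta[m]
        beta_dict[m] = {"intercept": b0, "slope": b1}
        if m == "sbp":
            beta_dict[m]["bp_med"] = -0.4
    return MlmmParams(
        spec=spec,
        beta=beta_dict,
        G=np.asarray(G, float),
        sigma2=np.asarray(sigma2, float),
        loglik=0.0,
        n_patients=0,
        n_obs=0,
        converged=True,
    )


def conditional_mvn_blup(params: MlmmParams, history: pd.DataFrame) -> np.ndarray:
    """Oracle: posterior mean of b by direct conditioning of the joint MVN.

    Builds the full joint covariance of (b, y) and conditions by block
    inversion; independent of the Woodbury-style path used in the package.
    """
    G = params.G
    sigma2 = params.sigma2
    rows = history.reset_index(drop=True)
    n = len(rows)
    if n == 0:
        return np.zeros(4)
    Z = np.zeros((n, 4))
    mean = np.zeros(n)
    R = np.zeros((n, n))
    for i, row in rows.iterrows():
        k = MARKERS.index(row["marker"])
        Z[i, k] = 1.0
        coefs = params.beta[row["marker"]]
        mean[i] = coefs["intercept"] + coefs["slope"] * row["t"]
        if row["marker"] == "sbp" and "bp_med" in coefs:
            mean[i] += coefs["bp_med"] * row.get("bp_med", 0)
        R[i, i] = sigma2[k]
    V = Z @ G @ Z.T + R
    y = rows["value"].to_numpy(float)
    return G @ Z.T @ np.linalg.solve(V, y - mean)


class TestBlup:
    def test_empty_history_gives_prior_mean(self, mlmm_truth):
        beta, G, sigma2 = mlmm_truth
        params = make_params(beta, G, sigma2)
        empty = pd.DataFrame(columns=["patient_id", "marker", "t", "value", "bp_med"])
        est = blup(params, empty)
        assert np.allclose(est.b_hat, 0.0)
        assert est.current_values[MARKERS.index("smoking")] == pytest.approx(0.30)
        est_tr = blup(params, empty, bp_med_at_s=1)
        assert est_tr.current_values[MARKERS.index("sbp")] == pytest.approx(0.10 - 0.4)

    def test_diagonal_G_single_marker_shrinkage_closed_form(self, mlmm_truth):
        beta, _, sigma2 = mlmm_truth
        G = np.diag([0.2, 0.5, 0.4, 0.3])
        params = make_params(beta, G, sigma2)
        m = 3
        ybar = 1.3
        hist = pd.DataFrame(
            {
                "patient_id": 0,
                "marker": "tchol",
                "t": [0.0] * m,
                "value": [ybar] * m,
                "bp_med": 0,
            }
        )
        k = MARKERS.index("tchol")
        est = blup(params, hist)
        expect = (G[k, k] / (G[k, k] + sigma2[k] / m)) * (ybar - beta["tchol"][0])
        assert est.b_hat[k] == pytest.approx(expect, abs=1e-12)

    def test_cross_marker_borrowing_matches_mvn_oracle(self, mlmm_truth):
        """Observing only SBP shifts the predicted cholesterol via the
        G covariance, matching direct MVN conditioning to 1e-8."""
        beta, G, sigma2 = mlmm_truth
        params = make_params(beta, G, sigma2)
        hist = pd.DataFrame(
            {
                "patient_id": 0,
                "marker": "sbp",
                "t": [-1.0, -0.2],
                "value": [1.5, 1.8],
                "bp_med": [0, 0],
            }
        )
        est = blup(params, hist)
        oracle = conditional_mvn_blup(params, hist)
        assert np.allclose(est.b_hat, oracle, atol=1e-8)
        k = MARKERS.index("tchol")
        assert est.b_hat[k] != 0.0  # borrowed strength

    def test_many_random_configs_match_mvn_oracle(self, mlmm_truth):
        """100 random (G, sigma2, history) configurations agree with the
        conditional-MVN oracle to 1e-8."""
        beta, _, _ = mlmm_truth
        rng = np.random.default_rng(42)
        for _ in range(100):
            A = rng.normal(size=(4, 4)) * 0.5
            G = A @ A.T + np.diag(rng.uniform(0.01, 0.5, 4))
            sigma2 = rng.uniform(0.05, 1.0, 4)
            params = make_params(beta, G, sigma2)
            n = rng.integers(0, 12)
            hist = pd.DataFrame(
                {
                    "patient_id": 0,
                    "marker": rng.choice(MARKERS, n),
                    "t": -rng.random(n) * 20,
                    "value": rng.normal(0, 1.5, n),
                    "bp_med": rng.integers(0, 2, n),
                }
            )
            est = blup(params, hist)
            oracle = conditional_mvn_blup(params, hist)
            assert np.allclose(est.b_hat, oracle, atol=1e-8)

    def test_shrinkage_grows_with_observations(self, mlmm_truth):
        beta, G, sigma2 = mlmm_truth
        params = make_params(beta, G, sigma2)
        k = MARKERS.index("sbp")
        resid = 2.0
        norms = []
        for m in (1, 5, 50, 500):
            hist = pd.DataFrame(
                {
                    "patient_id": 0,
                    "marker": "sbp",
                    "t": [0.0] * m,
                    "value": [beta["sbp"][0] + resid] * m,
                    "bp_med": 0,
                }
            )
            norms.append(abs(blup(params, hist).b_hat[k]))
        assert np.all(np.diff(norms) > 0)
        assert norms[-1] < resid  # never exceeds the unshrunken residual

    def test_zero_residual_gives_zero_blup(self, mlmm_truth):
        beta, G, sigma2 = mlmm_truth
        params = make_params(beta, G, sigma2)
        hist = pd.DataFrame(
            {
                "patient_id": 0,
                "marker": "sbp",
                "t": [0.0],
                "value": [beta["sbp"][0]],
                "bp_med": [0],
            }
        )
        assert blup(params, hist).b_hat[MARKERS.index("sbp")] == pytest.approx(0.0)

    def test_vanishing_noise_recovers_observation(self, mlmm_truth):
        beta, G, _ = mlmm_truth
        sigma2 = np.full(4, 1e-10)
        params = make_params(beta, G, sigma2)
        hist = pd.DataFrame(
            {"patient_id": 0, "marker": "sbp", "t": [0.0], "value": [1.7], "bp_med": [0]}
        )
        est = blup(params, hist)
        assert est.current_values[MARKERS.index("sbp")] == pytest.approx(1.7, abs=1e-6)


class TestFit:
    def test_degenerate_no_slope_no_G_is_ols(self):
        """With one observation per patient at t=0 the ML solution for the
        intercept is the pooled mean and sigma2 the ML (divisor n) variance."""
        rng = np.random.default_rng(1)
        n = 300
        vals = rng.normal(0.4, 0.8, n)
        df = pd.DataFrame(
            {
                "patient_id": np.arange(n),
                "marker": "tchol",
                "t": 0.0,
                "value": vals,
                "bp_med": 0,
            }
        )
        spec = MlmmSpec(s=60, sex="male")
        params = fit_mlmm_long(df, spec)
        # one obs per person: G and sigma2 are confounded; their sum is the
        # ML variance and the intercept the pooled mean
        k = MARKERS.index("tchol")
        total = params.G[k, k] + params.sigma2[k]
        assert params.beta["tchol"]["intercept"] == pytest.approx(vals.mean(), abs=1e-4)
        assert total == pytest.approx(vals.var(), rel=0.02)
        assert params.inestimable == [m for m in MARKERS if m != "tchol"]

    def test_single_marker_balanced_matches_anova_moments(self):
        """Balanced one-way random-effects layout: ML estimates agree with
        the closed-form moment estimators within optimizer tolerance."""
        rng = np.random.default_rng(2)
        n, m = 200, 4
        tau2, s2, mu = 0.5, 0.3, 1.0
        b = rng.normal(0, np.sqrt(tau2), n)
        y = mu + np.repeat(b, m) + rng.normal(0, np.sqrt(s2), n * m)
        df = pd.DataFrame(
            {
                "patient_id": np.repeat(np.arange(n), m),
                "marker": "sbp",
                "t": 0.0,
                "value": y,
                "bp_med": 0,
            }
        )
        params = fit_mlmm_long(df, MlmmSpec(s=60, sex="male"))
        k = MARKERS.index("sbp")
        ymat = y.reshape(n, m)
        within = ymat.var(axis=1, ddof=1).mean()
        between = ymat.mean(axis=1).var(ddof=1)
        tau2_mom = between - within / m
        assert params.beta["sbp"]["intercept"] == pytest.approx(y.mean(), abs=1e-3)
        assert params.sigma2[k] == pytest.approx(within, rel=0.05)
        assert params.G[k, k] == pytest.approx(tau2_mom, rel=0.10)

    def test_parameter_recovery_single_replicate(self, mlmm_truth):
        beta, G, sigma2 = mlmm_truth
        rng = np.random.default_rng(3)
        df, _ = simulate_mlmm_data(rng, 1000, beta, G, sigma2)
        params = fit_mlmm_long(df, MlmmSpec(s=60, sex="male"))
        assert params.converged
        for k, m in enumerate(MARKERS):
            assert params.beta[m]["intercept"] == pytest.approx(beta[m][0], abs=0.08)
            assert params.beta[m]["slope"] == pytest.approx(beta[m][1], abs=0.01)
            assert params.sigma2[k] == pytest.approx(sigma2[k], rel=0.15)
            assert params.G[k, k] == pytest.approx(G[k, k], rel=0.25)
        assert params.beta["sbp"]["bp_med"] == pytest.approx(-0.4, abs=0.1)

    def test_univariate_equivalence_when_G_diagonal(self, mlmm_truth):
        """Zero cross-marker correlation: joint fit and per-marker fits give
        the same current values within tolerance."""
        beta, _, sigma2 = mlmm_truth
        G = np.diag([0.2, 0.5, 0.4, 0.3])
        rng = np.random.default_rng(4)
        df, _ = simulate_mlmm_data(rng, 400, beta, G, sigma2)
        joint = fit_mlmm_long(df, MlmmSpec(s=60, sex="male"))
        hist0 = df[df["patient_id"] == 0]
        joint_blup = blup(joint, hist0, value_col="value")
        for m in MARKERS:
            single = fit_mlmm_long(
                df[df["marker"] == m], MlmmSpec(s=60, sex="male")
            )
            sb = blup(single, hist0[hist0["marker"] == m], value_col="value")
            k = MARKERS.index(m)
            assert sb.current_values[k] == pytest.approx(
                joint_blup.current_values[k], abs=0.05
            )

    def test_no_measurements_raises(self):
        df = pd.DataFrame(columns=["patient_id", "marker", "t", "value", "bp_med"])
        with pytest.raises(ValueError, match="not estimable"):
            fit_mlmm_long(df, MlmmSpec(s=60, sex="male"))

    def test_lookback_equivalence_when_data_within_window(self, mlmm_truth):
        beta, G, sigma2 = mlmm_truth
        rng = np.random.default_rng(5)
        df, _ = simulate_mlmm_data(rng, 200, beta, G, sigma2, t_span=8.0)
        p_inf = fit_mlmm_long(df, MlmmSpec(s=60, sex="male"))
        p_10 = fit_mlmm_long(df, MlmmSpec(s=60, sex="male", lookback_window=10.0))
        assert p_inf.loglik == pytest.approx(p_10.loglik, abs=1e-4)
        for m in MARKERS:
            assert p_inf.beta[m]["intercept"] == pytest.approx(
                p_10.beta[m]["intercept"], abs=1e-5
            )

    def test_reml_switch_gives_similar_estimates(self, mlmm_truth):
        beta, G, sigma2 = mlmm_truth
        rng = np.random.default_rng(7)
        df, _ = simulate_mlmm_data(rng, 300, beta, G, sigma2)
        ml = fit_mlmm_long(df, MlmmSpec(s=60, sex="male"))
        reml = fit_mlmm_long(df, MlmmSpec(s=60, sex="male", reml=True))
        assert reml.converged
        # REML corrects the downward ML bias of variance components
        for k in range(4):
            assert reml.sigma2[k] == pytest.approx(ml.sigma2[k], rel=0.10)
            assert reml.G[k, k] >= 0.8 * ml.G[k, k]

    def test_per_observation_likelihood_consistent_at_truth(self, mlmm_truth):
        """Per-observation log-likelihood at the true parameters is stable
        as the simulated sample doubles (law of large numbers)."""
        from ehrlandmark.mlmm import _SuffStats

        beta, G, sigma2 = mlmm_truth
        spec = MlmmSpec(s=60, sex="male")
        vals = []
        for n in (800, 1600):
            rng = np.random.default_rng(123)
            df, _ = simulate_mlmm_data(rng, n, beta, G, sigma2)
            stats = _SuffStats(df, spec, "value")
            neg2ll, _ = stats.profiled_neg2ll(sigma2, G)
            vals.append(-0.5 * neg2ll / stats.n_obs)
        assert vals[1] == pytest.approx(vals[0], abs=0.02)

    def test_params_json_round_trip(self, mlmm_truth):
        beta, G, sigma2 = mlmm_truth
        rng = np.random.default_rng(6)
        df, _ = simulate_mlmm_data(rng, 100, beta, G, sigma2)
        params = fit_mlmm_long(df, MlmmSpec(s=60, sex="male"))
        back = MlmmParams.from_json(params.to_json())
        assert np.allclose(back.G, params.G)
        assert back.beta == params.beta


def test_visit_rate_adjusted_fit_smoke(small_cohort):
    """The visit-rate-adjusted sensitivity model fits and predicts."""
    from ehrlandmark.cohort import build_landmark_dataset, fit_standardization
    from ehrlandmark.mlmm import fit_mlmm

    std = fit_standardization(small_cohort.measurements, small_cohort.df)
    meas_std = std.standardize(small_cohort.measurements, small_cohort.df)
    lds = build_landmark_dataset(60.0, small_cohort, meas_std)
    spec = MlmmSpec(s=60.0, sex="male", visit_rate_covariate=True)
    params = fit_mlmm(lds, "male", spec)
    assert params.converged
    for m in params.estimable:
        assert "visit_rate" in params.beta[m]
    values = estimate_current_values(params, lds)
    assert values[list(params.estimable)].notna().all().all()


class TestVisitRate:
    def test_rate_counts_window(self):
        h = pd.DataFrame({"marker": "sbp", "age": [56.0, 57.0, 59.5, 60.0, 61.0]})
        rate = annual_visit_rate(h, s=60.0)
        assert rate["sbp"] == pytest.approx(4 / 5)

    def test_empty_window_is_zero(self):
        h = pd.DataFrame({"marker": ["sbp"], "age": [40.0]})
        assert annual_visit_rate(h, s=60.0).get("sbp", 0.0) == 0.0

    def test_truncation_at_age_30(self):
        h = pd.DataFrame({"marker": "sbp", "age": [30.5, 31.0, 31.5, 32.0]})
        rate = annual_visit_rate(h, s=32.0)
        assert rate["sbp"] == pytest.approx(4 / 2)


class TestBatch:
    def test_mismatched_landmark_age_rejected(self, small_cohort, mlmm_truth):
        from ehrlandmark.cohort import build_landmark_dataset

        beta, G, sigma2 = mlmm_truth
        params = make_params(beta, G, sigma2, s=55.0)
        lds = build_landmark_dataset(60.0, small_cohort)
        with pytest.raises(ValueError, match="landmark age"):
            estimate_current_values(params, lds)

    def test_batch_equals_row_by_row(self, small_cohort, mlmm_truth):
        from ehrlandmark.cohort import build_landmark_dataset, fit_standardization
        from ehrlandmark.mlmm import fit_mlmm, prepare_stage1_data

        std = fit_standardization(small_cohort.measurements, small_cohort.df)
        meas_std = std.standardize(small_cohort.measurements, small_cohort.df)
        lds = build_landmark_dataset(60.0, small_cohort, meas_std)
        spec = MlmmSpec(s=60.0, sex="female")
        params = fit_mlmm(lds, "female", spec)
        batch = estimate_current_values(params, lds)
        long_df = prepare_stage1_data(lds, "female", spec)
        out = lds.outcomes[lds.outcomes["sex"] == "female"]
        for row in out.sample(10, random_state=0).itertuples():
            hist = long_df[long_df["patient_id"] == row.patient_id]
            single = blup(params, hist, bp_med_at_s=row.bp_med)
            for k, m in enumerate(MARKERS):
                got = batch.loc[row.patient_id, m]
                if np.isnan(single.current_values[k]):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(single.current_values[k], abs=1e-10)
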