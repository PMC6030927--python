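"""Stage 1: landmark-age multivariate linear mixed models and BLUPs.

For each landmark age ``s`` and sex we model all in-window measurements of
the four markers (smoking, SBP, total cholesterol, HDL-C) jointly.  With
time origin ``t = age - s`` (so t <= 0), marker ``k`` of person ``i``
follows::

    y_ikj = beta0_k + beta1_k * t_ikj + gamma * bp_med_ikj * [k == sbp]
            + b_ik + eps_ikj,
    b_i ~ MVN(0, G),   eps_ikj ~ N(0, sigma2_k) independent,

so the fixed-plus-random intercept ``beta0_k + b_ik`` *is* the error-free
current value at the landmark age.  The marginal likelihood is Gaussian
with per-person covariance ``V_i = Z_i G Z_i' + R_i``; because the random
effects are intercepts only, every quantity needed for the profiled
log-likelihood collapses to small per-person sufficient statistics
(per-marker counts, design cross-products and sums), making evaluation
O(n_persons) with 4x4 linear algebra regardless of how many measurements a
person has.

``G`` is parameterized through its Cholesky factor (log-diagonal) and the
residual variances through their logs, so the optimizer works on an
unconstrained scale; fixed effects are profiled out by generalized least
squares.  Estimation is maximum likelihood by default (REML available).

Empirical-Bayes prediction uses the identity
``b_hat_i = G (I + A_i G)^{-1} w_i`` with ``A_i = Z_i'R_i^{-1}Z_i`` (a
diagonal of per-marker counts over residual variances) and
``w_i = Z_i'R_i^{-1}(y_i - X_i beta)``, which is the posterior mean of the
random intercepts given the person's observed measurements and remains
valid for persons absent from the fitting data and for any subset of
observed markers (including none, where it returns the prior mean 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .config import MARKERS

__all__ = [
    "MlmmSpec",
    "MlmmParams",
    "BlupEstimate",
    "fit_mlmm",
    "fit_mlmm_long",
    "blup",
    "estimate_current_values",
    "annual_visit_rate",
    "prepare_stage1_data",
]


@dataclass
class MlmmSpec:
    """Stage-1 model options for one (landmark age, sex) stratum."""

    s: float
    sex: str
    markers: tuple[str, ...] = MARKERS
    lookback_window: float = float("inf")   # years before s; 10 in sensitivity
    visit_rate_covariate: bool = False      # annual rate in the 5 y before s
    reml: bool = False
    max_iter: int = 500

    def __post_init__(self) -> None:
        if self.lookback_window <= 0:
            raise ValueError("lookback_window must be > 0")


@dataclass
class MlmmParams:
    """Fitted stage-1 parameters for one (landmark age, sex) stratum.

    ``G`` and ``sigma2`` are indexed by ``spec.markers``; entries for
    markers with no measurements in the stratum are NaN and listed in
    ``inestimable``.
    """

    spec: MlmmSpec
    beta: dict[str, dict[str, float]]       # marker -> coefficient name -> value
    G: np.ndarray                           # 4x4
    sigma2: np.ndarray                      # (4,)
    loglik: float
    n_patients: int
    n_obs: int
    converged: bool
    inestimable: list[str] = field(default_factory=list)

    @property
    def estimable(self) -> list[str]:
        return [m for m in self.spec.markers if m not in self.inestimable]

    def to_json(self) -> str:
        return json.dumps(
            {
                "s": self.spec.s,
                "sex": self.spec.sex,
                "markers": list(self.spec.markers),
                "lookback_window": (
                    None if np.isinf(self.spec.lookback_window) else self.spec.lookback_window
                ),
                "visit_rate_covariate": self.spec.visit_rate_covariate,
                "reml": self.spec.reml,
                "beta": self.beta,
                "G": np.where(np.isnan(self.G), None, self.G).tolist(),
                "sigma2": [None if np.isnan(v) else v for v in self.sigma2],
                "loglik": self.loglik,
                "n_patients": self.n_patients,
                "n_obs": self.n_obs,
                "converged": self.converged,
                "inestimable": self.inestimable,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MlmmParams":
        d = json.loads(text)
        spec = MlmmSpec(
            s=d["s"],
            sex=d["sex"],
            markers=tuple(d["markers"]),
            lookback_window=d["lookback_window"] or float("inf"),
            visit_rate_covariate=d["visit_rate_covariate"],
            reml=d["reml"],
        )
        G = np.array([[np.nan if v is None else v for v in row] for row in d["G"]])
        sigma2 = np.array([np.nan if v is None else v for v in d["sigma2"]])
        return cls(
            spec=spec,
            beta=d["beta"],
            G=G,
            sigma2=sigma2,
            loglik=d["loglik"],
            n_patients=d["n_patients"],
            n_obs=d["n_obs"],
            converged=d["converged"],
            inestimable=d["inestimable"],
        )


@dataclass
class BlupEstimate:
    """Posterior-mean random intercepts and current values for one person."""

    patient_id: object
    b_hat: np.ndarray           # (4,) posterior means (0 when unobserved)
    current_values: np.ndarray  # (4,) mu_k(s); NaN for inestimable markers
    n_obs: np.ndarray           # (4,) per-marker observation counts used


def annual_visit_rate(
    history: pd.DataFrame, s: float, window: float = 5.0, per_marker: bool = True
):
    """Annual measurement rate in the ``window`` years before ``s``.

    Counts measurements with age in (s - window, s], divided by the window
    length truncated at age 30.  Returns a per-marker Series (or a float
    when ``per_marker`` is False).
    """
    lo = max(s - window, 30.0)
    length = s - lo
    if length <= 0:
        return (
            pd.Series(0.0, index=pd.Index(history["marker"].unique(), name="marker"))
            if per_marker
            else 0.0
        )
    in_win = history[(history["age"] > lo) & (history["age"] <= s + 1e-12)]
    if per_marker:
        return in_win.groupby("marker").size() / length
    return len(in_win) / length


def _design_columns(marker: str, spec: MlmmSpec) -> list[str]:
    cols = ["intercept", "slope"]
    if marker == "sbp":
        cols.append("bp_med")
    if spec.visit_rate_covariate:
        cols.append("visit_rate")
    return cols


def _design_matrix(marker: str, sub: pd.DataFrame, spec: MlmmSpec) -> np.ndarray:
    cols = [np.ones(len(sub)), sub["t"].to_numpy(float)]
    if marker == "sbp":
        cols.append(sub["bp_med"].to_numpy(float) if "bp_med" in sub else np.zeros(len(sub)))
    if spec.visit_rate_covariate:
        cols.append(sub["visit_rate"].to_numpy(float))
    return np.column_stack(cols)


class _SuffStats:
    """Per-person sufficient statistics of the stacked long data."""

    def __init__(self, long_df: pd.DataFrame, spec: MlmmSpec, value_col: str):
        self.spec = spec
        est = [m for m in spec.markers if (long_df["marker"] == m).any()]
        self.markers = est
        self.K = len(est)
        ids = np.sort(long_df["patient_id"].unique())
        self.patient_ids = ids
        self.N = len(ids)
        pos = pd.Series(np.arange(self.N), index=ids)
        self.pcols: dict[str, list[str]] = {m: _design_columns(m, spec) for m in est}

        self.counts = np.zeros((self.N, self.K))
        self.Sxx, self.Sxy, self.Syy, self.sx, self.sy = {}, {}, {}, {}, {}
        self.Sxx_tot, self.Sxy_tot, self.Syy_tot = {}, {}, {}
        self.n_obs = 0
        for k, m in enumerate(est):
            sub = long_df[long_df["marker"] == m]
            X = _design_matrix(m, sub, spec)
            y = sub[value_col].to_numpy(float)
            idx = pos[sub["patient_id"]].to_numpy()
            p = X.shape[1]
            self.n_obs += len(y)
            np.add.at(self.counts[:, k], idx, 1.0)
            Sxx = np.zeros((self.N, p, p))
            np.add.at(Sxx, idx, X[:, :, None] * X[:, None, :])
            Sxy = np.zeros((self.N, p))
            np.add.at(Sxy, idx, X * y[:, None])
            Syy = np.zeros(self.N)
            np.add.at(Syy, idx, y * y)
            sx = np.zeros((self.N, p))
            np.add.at(sx, idx, X)
            sy = np.zeros(self.N)
            np.add.at(sy, idx, y)
            self.Sxx[m], self.Sxy[m], self.Syy[m] = Sxx, Sxy, Syy
            self.sx[m], self.sy[m] = sx, sy
            self.Sxx_tot[m] = Sxx.sum(axis=0)
            self.Sxy_tot[m] = Sxy.sum(axis=0)
            self.Syy_tot[m] = float(Syy.sum())
        self.p_per = [self.Sxx_tot[m].shape[0] for m in est]
        self.P = sum(self.p_per)
        self.offsets = np.concatenate([[0], np.cumsum(self.p_per)])

    def profiled_neg2ll(self, sigma2: np.ndarray, G: np.ndarray):
        """Profiled -2 log-likelihood; returns (value, beta_hat)."""
        K, N, P = self.K, self.N, self.P
        A = self.counts / sigma2  # (N, K)
        B = np.eye(K)[None] + A[:, :, None] * G[None]  # I + diag(A) G
        sign, logdetB = np.linalg.slogdet(B)
        if np.any(sign <= 0):
            return np.inf, None
        invB = np.linalg.inv(B)
        M = np.einsum("kl,nlm->nkm", G, invB)  # G (I + A G)^{-1}, symmetric

        XtViX = np.zeros((P, P))
        XtViy = np.zeros(P)
        for k, mk in enumerate(self.markers):
            o_k = slice(self.offsets[k], self.offsets[k + 1])
            XtViX[o_k, o_k] += self.Sxx_tot[mk] / sigma2[k]
            XtViy[o_k] += self.Sxy_tot[mk] / sigma2[k]
            for l, ml in enumerate(self.markers):
                o_l = slice(self.offsets[l], self.offsets[l + 1])
                # Correction is U' M U with U_i rows = A_i-weighted design sums.
                w = M[:, k, l] / (sigma2[k] * sigma2[l])
                XtViX[o_k, o_l] -= np.einsum("n,np,nq->pq", w, self.sx[mk], self.sx[ml])
                XtViy[o_k] -= np.einsum("n,np->p", w * self.sy[ml], self.sx[mk])
        try:
            c = np.linalg.cond(XtViX)
            if not np.isfinite(c) or c > 1e10:
                raise np.linalg.LinAlgError
            beta = np.linalg.solve(XtViX, XtViy)
        except np.linalg.LinAlgError:
            # rank-deficient fixed-effect design (e.g. a marker observed at a
            # single time point); minimum-norm GLS solution
            beta = np.linalg.pinv(XtViX, rcond=1e-10) @ XtViy

        quad = 0.0
        wres = np.zeros((N, K))
        for k, mk in enumerate(self.markers):
            bk = beta[self.offsets[k]: self.offsets[k + 1]]
            quad += (
                self.Syy_tot[mk]
                - 2.0 * bk @ self.Sxy_tot[mk]
                + bk @ self.Sxx_tot[mk] @ bk
            ) / sigma2[k]
            wres[:, k] = (self.sy[mk] - self.sx[mk] @ bk) / sigma2[k]
        quad -= np.einsum("nkl,nk,nl->", M, wres, wres)

        n_tot = self.n_obs
        val = (
            n_tot * np.log(2.0 * np.pi)
            + float(self.counts.sum(axis=0) @ np.log(sigma2))
            + float(logdetB.sum())
            + quad
        )
        if self.spec.reml:
            sgn, ld = np.linalg.slogdet(XtViX)
            if sgn <= 0:
                return np.inf, None
            val += ld - P * np.log(2.0 * np.pi)
        return val, beta


def _unpack(theta: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray]:
    sigma2 = np.exp(np.clip(theta[:K], -30, 30))
    L = np.zeros((K, K))
    L[np.diag_indices(K)] = np.exp(np.clip(theta[K: 2 * K], -30, 30))
    if K > 1:
        L[np.tril_indices(K, -1)] = theta[2 * K:]
    return sigma2, L @ L.T


def _pack(sigma2: np.ndarray, G: np.ndarray) -> np.ndarray:
    K = len(sigma2)
    jitter = 1e-6 * np.eye(K)
    L = np.linalg.cholesky(G + jitter)
    parts = [np.log(sigma2), np.log(np.diag(L))]
    if K > 1:
        parts.append(L[np.tril_indices(K, -1)])
    return np.concatenate(parts)


def _moment_start(stats: _SuffStats) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker OLS + one-way variance decomposition starting values."""
    K = stats.K
    sigma2 = np.ones(K)
    Gdiag = 0.3 * np.ones(K)
    for k, m in enumerate(stats.markers):
        XtX, Xty = stats.Sxx_tot[m], stats.Sxy_tot[m]
        try:
            bk = np.linalg.solve(XtX + 1e-8 * np.eye(len(Xty)), Xty)
        except np.linalg.LinAlgError:
            continue
        n_k = stats.counts[:, k]
        obs = n_k > 0
        rss = stats.Syy_tot[m] - 2 * bk @ Xty + bk @ XtX @ bk
        tot_var = max(rss / max(n_k.sum(), 1.0), 1e-4)
        # between-person variance from per-person mean residuals
        mean_res = np.zeros(stats.N)
        mean_res[obs] = (stats.sy[m][obs] - stats.sx[m][obs] @ bk) / n_k[obs]
        between = float(np.var(mean_res[obs])) if obs.sum() > 1 else 0.0
        m_bar = float(n_k[obs].mean()) if obs.any() else 1.0
        sigma2[k] = max(tot_var - max(between - tot_var / m_bar, 0.0), 0.25 * tot_var)
        Gdiag[k] = max(between - sigma2[k] / m_bar, 0.05 * tot_var)
    return sigma2, np.diag(Gdiag)


def fit_mlmm_long(
    long_df: pd.DataFrame, spec: MlmmSpec, value_col: str | None = None
) -> MlmmParams:
    """Fit the multivariate LMM to a prepared long table.

    ``long_df`` needs columns ``patient_id, marker, t, value(_std)`` plus
    ``bp_med`` (treatment status at measurement time) and, when the spec
    enables it, ``visit_rate``.  Rows outside the lookback window are
    dropped here; persons with no remaining rows contribute nothing.
    """
    if value_col is None:
        value_col = "value_std" if "value_std" in long_df.columns else "value"
    df = long_df[long_df["t"] <= 1e-12]
    if np.isfinite(spec.lookback_window):
        df = df[df["t"] >= -spec.lookback_window - 1e-12]
    df = df[df["marker"].isin(spec.markers)]
    if not len(df):
        raise ValueError("no measurements in window: stage-1 model not estimable")

    stats = _SuffStats(df, spec, value_col)
    K = stats.K

    def objective(theta: np.ndarray) -> float:
        sigma2, G = _unpack(theta, K)
        val, _ = stats.profiled_neg2ll(sigma2, G)
        return 0.5 * val if np.isfinite(val) else 1e12

    s2_mom, G_mom = _moment_start(stats)
    starts = [_pack(s2_mom, G_mom), _pack(s2_mom, 0.3 * np.eye(K))]
    best = None
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            options={"maxiter": spec.max_iter, "ftol": 1e-11, "gtol": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res
    sigma2, G = _unpack(best.x, K)
    val, beta_vec = stats.profiled_neg2ll(sigma2, G)
    converged = bool(best.success) and beta_vec is not None
    if beta_vec is None:
        raise RuntimeError("stage-1 likelihood degenerate at optimum")

    beta: dict[str, dict[str, float]] = {}
    for k, m in enumerate(stats.markers):
        coefs = beta_vec[stats.offsets[k]: stats.offsets[k + 1]]
        beta[m] = dict(zip(stats.pcols[m], map(float, coefs)))

    K4 = len(spec.markers)
    G_full = np.full((K4, K4), np.nan)
    s2_full = np.full(K4, np.nan)
    est_idx = [spec.markers.index(m) for m in stats.markers]
    for a, ka in enumerate(est_idx):
        s2_full[ka] = sigma2[a]
        for b, kb in enumerate(est_idx):
            G_full[ka, kb] = G[a, b]
    inest = [m for m in spec.markers if m not in stats.markers]
    return MlmmParams(
        spec=spec,
        beta=beta,
        G=G_full,
        sigma2=s2_full,
        loglik=-0.5 * val,
        n_patients=stats.N,
        n_obs=stats.n_obs,
        converged=converged,
        inestimable=inest,
    )


def prepare_stage1_data(lds, sex: str, spec: MlmmSpec) -> pd.DataFrame:
    """Long table of one sex's in-window history rows for fitting/BLUPs."""
    ids = set(lds.outcomes.loc[lds.outcomes["sex"] == sex, "patient_id"])
    df = lds.history[lds.history["patient_id"].isin(ids)].copy()
    if spec.visit_rate_covariate and len(df):
        rates = (
            df.groupby(["patient_id", "marker"])
            .apply(lambda g: annual_visit_rate(g, spec.s, per_marker=False), include_groups=False)
            .rename("visit_rate")
            .reset_index()
        )
        df = df.merge(rates, on=["patient_id", "marker"], how="left")
        df["visit_rate"] = df["visit_rate"].fillna(0.0)
    return df


def fit_mlmm(lds, sex: str, spec: MlmmSpec) -> MlmmParams:
    """Fit the stage-1 model on a landmark dataset for one sex."""
    if abs(spec.s - lds.s) > 1e-9:
        raise ValueError(f"spec landmark age {spec.s} != dataset landmark age {lds.s}")
    return fit_mlmm_long(prepare_stage1_data(lds, sex, spec), spec)


# ---------------------------------------------------------------------------
# Empirical-Bayes prediction
# ---------------------------------------------------------------------------

def _residuals(params: MlmmParams, history: pd.DataFrame, value_col: str):
    """Per-marker counts and residual sums (y - X beta) for one person."""
    spec = params.spec
    K4 = len(spec.markers)
    n = np.zeros(K4)
    rsum = np.zeros(K4)
    df = history[history["t"] <= 1e-12]
    if np.isfinite(spec.lookback_window):
        df = df[df["t"] >= -spec.lookback_window - 1e-12]
    for k, m in enumerate(spec.markers):
        if m in params.inestimable:
            continue
        sub = df[df["marker"] == m]
        if not len(sub):
            continue
        X = _design_matrix(m, sub, spec)
        bk = np.array([params.beta[m][c] for c in _design_columns(m, spec)])
        r = sub[value_col].to_numpy(float) - X @ bk
        n[k] = len(sub)
        rsum[k] = r.sum()
    return n, rsum


def blup(
    params: MlmmParams,
    history: pd.DataFrame,
    bp_med_at_s: int = 0,
    visit_rates: dict[str, float] | None = None,
    patient_id=None,
    value_col: str | None = None,
) -> BlupEstimate:
    """Empirical-Bayes prediction for one person (possibly out-of-sample).

    ``history`` holds the person's measurement rows (columns as in
    :func:`fit_mlmm_long`; may be empty).  ``bp_med_at_s`` is the
    carried-forward treatment flag at the landmark age and enters the SBP
    current value through the fitted treatment coefficient.
    """
    if value_col is None:
        value_col = "value_std" if "value_std" in history.columns else "value"
    spec = params.spec
    est = params.estimable
    idx = [spec.markers.index(m) for m in est]
    n, rsum = _residuals(params, history, value_col)
    G = params.G[np.ix_(idx, idx)]
    s2 = params.sigma2[idx]
    A = n[idx] / s2
    w = rsum[idx] / s2
    K = len(idx)
    B = np.eye(K) + A[:, None] * G
    cond = np.linalg.cond(B)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"BLUP system ill-conditioned (cond={cond:.3g}) at s={spec.s}"
        )
    b_sub = G @ np.linalg.solve(B, w)
    b_hat = np.zeros(len(spec.markers))
    for a, ka in enumerate(idx):
        b_hat[ka] = b_sub[a]

    current = np.full(len(spec.markers), np.nan)
    for k, m in enumerate(spec.markers):
        if m in params.inestimable:
            continue
        mu = params.beta[m]["intercept"] + b_hat[k]
        if m == "sbp" and "bp_med" in params.beta[m]:
            mu += params.beta[m]["bp_med"] * bp_med_at_s
        if spec.visit_rate_covariate and "visit_rate" in params.beta[m]:
            rate = (visit_rates or {}).get(m, 0.0)
            mu += params.beta[m]["visit_rate"] * rate
        current[k] = mu
    return BlupEstimate(patient_id=patient_id, b_hat=b_hat, current_values=current, n_obs=n)


def estimate_current_values(params: MlmmParams, lds) -> pd.DataFrame:
    """Batch BLUP current values for every eligible person of the stratum.

    Returns a table indexed by patient_id with one column per marker plus
    per-marker ``n_obs_*`` counts; persons with no in-window measurements
    receive the fixed-effects (prior-mean) prediction.
    """
    if abs(params.spec.s - lds.s) > 1e-9:
        raise ValueError(
            f"params landmark age {params.spec.s} != dataset landmark age {lds.s}"
        )
    spec = params.spec
    out_rows = lds.outcomes[lds.outcomes["sex"] == spec.sex]
    long_df = prepare_stage1_data(lds, spec.sex, spec)
    value_col = "value_std" if "value_std" in long_df.columns else "value"

    pids = out_rows["patient_id"].to_numpy()
    N = len(pids)
    pos = pd.Series(np.arange(N), index=pids)
    K4 = len(spec.markers)
    n = np.zeros((N, K4))
    rsum = np.zeros((N, K4))
    rates = np.zeros((N, K4))

    df = long_df[long_df["t"] <= 1e-12]
    if np.isfinite(spec.lookback_window):
        df = df[df["t"] >= -spec.lookback_window - 1e-12]
    win_lo = max(spec.s - 5.0, 30.0)
    win_len = spec.s - win_lo
    for k, m in enumerate(spec.markers):
        if m in params.inestimable:
            continue
        sub = df[df["marker"] == m]
        if not len(sub):
            continue
        X = _design_matrix(m, sub, spec)
        bk = np.array([params.beta[m][c] for c in _design_columns(m, spec)])
        r = sub[value_col].to_numpy(float) - X @ bk
        idx = pos[sub["patient_id"]].to_numpy()
        np.add.at(n[:, k], idx, 1.0)
        np.add.at(rsum[:, k], idx, r)
        if spec.visit_rate_covariate and win_len > 0:
            in_win = (sub["age"] > win_lo) & (sub["age"] <= spec.s + 1e-12)
            np.add.at(rates[:, k], idx[in_win.to_numpy()], 1.0 / win_len)

    est = params.estimable
    idx_e = [spec.markers.index(m) for m in est]
    G = params.G[np.ix_(idx_e, idx_e)]
    s2 = params.sigma2[idx_e]
    A = n[:, idx_e] / s2
    w = rsum[:, idx_e] / s2
    K = len(idx_e)
    B = np.eye(K)[None] + A[:, :, None] * G[None]
    b_sub = np.einsum("kl,nl->nk", G, np.linalg.solve(B, w[:, :, None])[:, :, 0])

    b_hat = np.zeros((N, K4))
    b_hat[:, idx_e] = b_sub
    bp_flag = out_rows["bp_med"].to_numpy(float)
    result = {"patient_id": pids}
    for k, m in enumerate(spec.markers):
        if m in params.inestimable:
            result[m] = np.full(N, np.nan)
        else:
            mu = params.beta[m]["intercept"] + b_hat[:, k]
            if m == "sbp" and "bp_med" in params.beta[m]:
                mu = mu + params.beta[m]["bp_med"] * bp_flag
            if spec.visit_rate_covariate and "visit_rate" in params.beta[m]:
                mu = mu + params.beta[m]["visit_rate"] * rates[:, k]
            result[m] = mu
        result[f"n_obs_{m}"] = n[:, k].astype(int)
    return pd.DataFrame(result).set_index("patient_id")
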