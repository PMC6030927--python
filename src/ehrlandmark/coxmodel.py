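"""Stage 2: super-landmark Cox model and 10-year risk prediction.

The per-landmark covariate tables are stacked across landmark ages
(40, 45, ..., 85) into one dataset with time-since-landmark as the
survival clock (capped at the 10-year horizon).  A single Cox proportional
hazards model is fitted to the stack, stratified by sex, with robust
(patient-clustered sandwich) standard errors to account for the same
person contributing rows at several landmark ages.  Ten-year risk is
``1 - exp(-Lambda0_sex(10) * exp(x' theta))`` with the per-stratum Breslow
cumulative baseline hazard ``Lambda0``.

Landmark age enters as ``age_z = (s - 60)/10`` and its square for
optimizer conditioning; hazard ratios for age are therefore per decade.

The partial likelihood uses Breslow tie handling, under which duplicating
every row of the data leaves the point estimate and the patient-clustered
sandwich variance exactly unchanged — the natural behaviour for stacked
landmark data where the same person (and the same event) legitimately
recurs at several landmark ages.  Maximization is by Newton-Raphson with
step halving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MARKERS

VARIANTS = ("basic", "current_values", "age_interactions", "last_observed", "cumulative_mean")

_ID_COLS = ["patient_id", "practice_id", "sex", "s", "time", "event"]


def make_covariates(
    lds,
    marker_values: pd.DataFrame | None,
    variant: str,
) -> pd.DataFrame:
    """Build one landmark age's covariate table for a model variant.

    ``marker_values`` is a table indexed by patient_id with one column per
    marker: stage-1 current values for the ``current_values`` /
    ``age_interactions`` variants, or the last-observed / cumulative-mean
    summaries for the comparator variants (ignored for ``basic``).  For the
    comparator variants rows with any missing marker are dropped — the
    "restricted sample" of persons with at least one measurement of every
    marker.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    out = lds.outcomes.copy()
    age_z = (lds.s - 60.0) / 10.0
    out["age_z"] = age_z
    out["age_z2"] = age_z ** 2
    base_covs = ["age_z", "age_z2", "diabetes", "bp_med"]
    if variant == "basic":
        return out[_ID_COLS + base_covs]

    if marker_values is None:
        raise ValueError(f"variant {variant!r} requires marker values")
    mv = marker_values.reindex(out["patient_id"])[list(MARKERS)].to_numpy(float)
    for k, m in enumerate(MARKERS):
        out[m] = mv[:, k]
    covs = base_covs + list(MARKERS)
    if variant in ("last_observed", "cumulative_mean"):
        out = out.dropna(subset=list(MARKERS))
    else:
        if out[list(MARKERS)].isna().any().any():
            raise ValueError(
                "stage-1 current values contain missing entries; the prior-mean "
                "fallback should make this impossible"
            )
    if variant == "age_interactions":
        for c in covs.copy():
            out[f"{c}_x_age"] = out[c] * age_z
            covs.append(f"{c}_x_age")
    return out[_ID_COLS + covs]


def stack_landmarks(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-landmark covariate tables into the super-landmark set."""
    if not tables:
        raise ValueError("no covariate tables to stack")
    cols = list(tables[0].columns)
    for t in tables[1:]:
        if list(t.columns) != cols:
            raise ValueError("covariate tables have mismatched schemas")
    stacked = pd.concat(tables, ignore_index=True)
    dup = stacked.duplicated(subset=["patient_id", "s"])
    if dup.any():
        pid, s = stacked.loc[dup.idxmax(), ["patient_id", "s"]]
        raise ValueError(f"duplicate (patient, landmark) row: patient {pid} at s={s}")
    return stacked


@dataclass
class CoxFit:
    """Fitted super-landmark Cox model."""

    variant: str
    covariates: list[str]
    theta: pd.Series                       # log hazard ratios
    cov_model: pd.DataFrame                # model-based covariance
    cov_robust: pd.DataFrame               # patient-clustered sandwich
    baseline: dict[str, pd.DataFrame]      # sex -> (time, cumhaz) step function
    n_rows: int
    n_events: int
    meta: dict = field(default_factory=dict)

    def baseline_cumhaz(self, sex: str, t: float) -> float:
        """Breslow cumulative baseline hazard Lambda0_sex(t)."""
        if sex not in self.baseline:
            raise KeyError(f"no baseline hazard for stratum {sex!r}")
        bl = self.baseline[sex]
        idx = np.searchsorted(bl["time"].to_numpy(), t, side="right") - 1
        return float(bl["cumhaz"].iloc[idx]) if idx >= 0 else 0.0

    def robust_se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_robust)), index=self.theta.index)


def _breslow_baseline(
    df: pd.DataFrame, theta: pd.Series, covariates: list[str]
) -> dict[str, pd.DataFrame]:
    """Per-stratum Breslow estimator of the cumulative baseline hazard."""
    out = {}
    for sex, grp in df.groupby("sex", observed=True):
        lp = grp[covariates].to_numpy(float) @ theta.to_numpy()
        risk = np.exp(lp)
        t = grp["time"].to_numpy(float)
        e = grp["event"].to_numpy(int)
        order = np.argsort(t, kind="stable")
        t, e, risk = t[order], e[order], risk[order]
        # risk set sum at time u = sum of risk over t >= u (right-continuous)
        rev_cum = np.cumsum(risk[::-1])[::-1]
        ev_times, counts = np.unique(t[e == 1], return_counts=True)
        if len(ev_times) == 0:
            out[sex] = pd.DataFrame({"time": [0.0], "cumhaz": [0.0]})
            continue
        denom = rev_cum[np.searchsorted(t, ev_times, side="left")]
        increments = counts / denom
        out[sex] = pd.DataFrame(
            {"time": ev_times, "cumhaz": np.cumsum(increments)}
        )
    return out


def _stratum_arrays(rows: pd.DataFrame, covariates: list[str], strata: str):
    """Per-stratum (X, t, e, row index) sorted by ascending time."""
    out = []
    for _, grp in rows.groupby(strata, observed=True):
        order = np.argsort(grp["time"].to_numpy(), kind="stable")
        g = grp.iloc[order]
        out.append(
            (
                g[covariates].to_numpy(float),
                g["time"].to_numpy(float),
                g["event"].to_numpy(int),
                g.index.to_numpy(),
            )
        )
    return out


def _breslow_ll_grad_hess(theta: np.ndarray, strata_data) -> tuple[float, np.ndarray, np.ndarray]:
    """Breslow partial log-likelihood with analytic score and hessian.

    Risk-set sums S0, S1, S2 are reverse cumulative sums over the
    time-sorted rows, evaluated at each distinct event time.
    """
    p = len(theta)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for X, t, e, _ in strata_data:
        eta = X @ theta
        eta = np.clip(eta, -500, 500)
        w = np.exp(eta)
        wX = w[:, None] * X
        wXX = wX[:, :, None] * X[:, None, :]
        S0 = np.cumsum(w[::-1])[::-1]
        S1 = np.cumsum(wX[::-1], axis=0)[::-1]
        S2 = np.cumsum(wXX[::-1], axis=0)[::-1]
        ev_times = np.unique(t[e == 1])
        idx = np.searchsorted(t, ev_times, side="left")
        # events and event-covariate sums per distinct event time
        d = np.zeros(len(ev_times))
        sX = np.zeros((len(ev_times), p))
        pos = np.searchsorted(ev_times, t[e == 1])
        np.add.at(d, pos, 1.0)
        np.add.at(sX, pos, X[e == 1])
        s0 = S0[idx]
        xbar = S1[idx] / s0[:, None]
        ll += float((sX @ theta).sum() - (d * np.log(s0)).sum())
        grad += sX.sum(axis=0) - (d[:, None] * xbar).sum(axis=0)
        v = S2[idx] / s0[:, None, None] - xbar[:, :, None] * xbar[:, None, :]
        hess -= (d[:, None, None] * v).sum(axis=0)
    return ll, grad, hess


def _score_residuals(theta: np.ndarray, strata_data, n_rows: int) -> np.ndarray:
    """Per-row score residuals (for the clustered sandwich variance)."""
    p = len(theta)
    U = np.zeros((n_rows, p))
    for X, t, e, ridx in strata_data:
        eta = np.clip(X @ theta, -500, 500)
        w = np.exp(eta)
        wX = w[:, None] * X
        S0 = np.cumsum(w[::-1])[::-1]
        S1 = np.cumsum(wX[::-1], axis=0)[::-1]
        ev_times = np.unique(t[e == 1])
        idx = np.searchsorted(t, ev_times, side="left")
        d = np.zeros(len(ev_times))
        pos = np.searchsorted(ev_times, t[e == 1])
        np.add.at(d, pos, 1.0)
        s0 = S0[idx]
        xbar = S1[idx] / s0[:, None]
        # cumulative hazard-type sums H0(t) = sum_{t_j<=t} d_j/S0_j and
        # H1(t) = sum d_j xbar_j / S0_j, evaluated at each row's time
        h0_steps = d / s0
        h1_steps = (d / s0)[:, None] * xbar
        H0 = np.concatenate([[0.0], np.cumsum(h0_steps)])
        H1 = np.vstack([np.zeros(p), np.cumsum(h1_steps, axis=0)])
        k = np.searchsorted(ev_times, t, side="right")
        res = -w[:, None] * (X * H0[k][:, None] - H1[k])
        ev = e == 1
        res[ev] += X[ev] - xbar[np.searchsorted(ev_times, t[ev])]
        U[ridx] = res
    return U


def fit_cox(
    rows: pd.DataFrame,
    variant: str = "current_values",
    cluster: str = "patient_id",
    strata: str = "sex",
    max_iter: int = 200,
    tol: float = 1e-10,
) -> CoxFit:
    """Fit the sex-stratified Cox model to the stacked landmark rows.

    Newton-Raphson maximization of the Breslow partial likelihood with
    step halving.  The robust covariance aggregates score residuals within
    ``cluster`` (patients recur across landmark ages); the model-based
    covariance is the inverse observed information.  Raises on strata
    without events, constant covariates, and monotone likelihood
    (perfect separation).
    """
    covariates = [c for c in rows.columns if c not in _ID_COLS]
    if not covariates:
        raise ValueError("no covariates to fit")
    for sex, grp in rows.groupby(strata, observed=True):
        if grp["event"].sum() == 0:
            raise ValueError(f"stratum {sex!r} has no events")
    for c in covariates:
        if rows[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} is constant; no information")
    if (rows["time"] <= 0).any():
        raise ValueError("nonpositive follow-up time in stacked rows")

    work = rows.reset_index(drop=True)
    strata_data = _stratum_arrays(work, covariates, strata)
    p = len(covariates)
    theta = np.zeros(p)
    ll, grad, hess = _breslow_ll_grad_hess(theta, strata_data)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as err:
            raise RuntimeError(f"singular information matrix ({variant})") from err
        # step halving to guarantee ascent
        alpha = 1.0
        for _ in range(30):
            cand = theta + alpha * step
            ll_new, g_new, h_new = _breslow_ll_grad_hess(cand, strata_data)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            alpha *= 0.5
        theta, ll, grad, hess = cand, ll_new, g_new, h_new
        if np.abs(theta).max() > 50:
            raise RuntimeError(
                f"monotone partial likelihood (perfect separation) in {variant}"
            )
        if np.abs(alpha * step).max() < tol and np.abs(grad).max() < 1e-6:
            break
    else:
        raise RuntimeError(f"Cox fit did not converge in {max_iter} iterations")

    info_inv = np.linalg.inv(-hess)
    U = _score_residuals(theta, strata_data, len(work))
    cl = work[cluster].to_numpy()
    Uc = pd.DataFrame(U).groupby(cl).sum().to_numpy()
    meat = Uc.T @ Uc
    robust = info_inv @ meat @ info_inv

    theta_s = pd.Series(theta, index=covariates)
    baseline = _breslow_baseline(work, theta_s, covariates)
    return CoxFit(
        variant=variant,
        covariates=covariates,
        theta=theta_s,
        cov_model=pd.DataFrame(info_inv, index=covariates, columns=covariates),
        cov_robust=pd.DataFrame(robust, index=covariates, columns=covariates),
        baseline=baseline,
        n_rows=len(work),
        n_events=int(work["event"].sum()),
        meta={"log_likelihood": ll},
    )


def predict_10y_risk(
    fit: CoxFit, rows: pd.DataFrame, horizon: float = 10.0
) -> pd.DataFrame:
    """Predicted risk within ``horizon`` years of the landmark age.

    ``rows`` must carry the fit's covariate columns and a ``sex`` column;
    returns patient_id (if present), s, lp and risk10.
    """
    missing = [c for c in fit.covariates if c not in rows.columns]
    if missing:
        raise ValueError(f"rows lack covariates {missing}")
    unknown = set(rows["sex"].unique()) - set(fit.baseline)
    if unknown:
        raise KeyError(f"sex stratum {unknown} absent from fit")
    lp = rows[fit.covariates].to_numpy(float) @ fit.theta.to_numpy()
    lam = np.array([fit.baseline_cumhaz(sx, horizon) for sx in rows["sex"]])
    risk = 1.0 - np.exp(-lam * np.exp(lp))
    out = pd.DataFrame({"lp": lp, "risk10": risk}, index=rows.index)
    for c in ("patient_id", "s", "sex", "time", "event", "practice_id"):
        if c in rows.columns:
            out[c] = rows[c].to_numpy()
    return out
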