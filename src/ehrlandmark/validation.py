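"""Predictive-performance measures and cross-validation.

Metrics operate on pooled prediction tables with one row per
(patient, landmark age): predicted 10-year risk, follow-up time since the
landmark (capped at the horizon) and the event indicator.

* Brier score: mean squared difference between predicted risk and the
  10-year outcome.  The default handles censoring by inverse probability
  of censoring weighting (IPCW) with a Kaplan-Meier estimate of the
  censoring distribution; ``mode="complete_case"`` averages over subjects
  whose 10-year status is known, which coincides with IPCW when no one is
  censored before the horizon.
* C-index (Harrell): fraction of comparable pairs ordered correctly by the
  predicted risk, with 1/2 credit for score ties.  Pairs sharing a
  patient_id are excluded (the stacked data repeats individuals); the
  age-adjusted version restricts comparisons to rows at the same landmark
  age.
* Calibration: mean predicted risk versus 1 - KM(horizon) within deciles
  of predicted risk.

Cross-validation splits whole general practices into k folds: per fold,
standardization, stage-1 mixed models and the stage-2 Cox fit use training
practices only; held-out individuals receive out-of-sample empirical-Bayes
predictions from the training parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from . import cohort as cohort_mod
from . import coxmodel, mlmm
from .config import MARKERS, PipelineConfig

__all__ = [
    "brier_score",
    "harrell_cindex",
    "cindex_by_landmark_age",
    "calibration_deciles",
    "ValidationReport",
    "validate_predictions",
    "cross_validate",
    "compare_models",
]


def _km_survival(times, events) -> KaplanMeierFitter:
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    return kmf


def brier_score(
    predictions, times, events, horizon: float = 10.0, mode: str = "ipcw"
) -> float:
    """Brier score for the binary within-horizon outcome.

    IPCW weighting (Graf): subjects with an event at ``T <= horizon`` get
    weight ``1/G(T-)``, subjects followed past the horizon get
    ``1/G(horizon-)``, subjects censored earlier get 0, where ``G`` is the
    Kaplan-Meier estimate of the censoring survival function.
    """
    p = np.asarray(predictions, float)
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("predictions must lie in [0, 1]")
    event_by_h = (e == 1) & (t <= horizon)
    past_h = t >= horizon
    if mode == "complete_case":
        known = event_by_h | past_h
        if not known.any():
            raise ValueError("no subject has known horizon status")
        outcome = event_by_h[known].astype(float)
        return float(np.mean((p[known] - outcome) ** 2))
    if mode != "ipcw":
        raise ValueError(f"unknown mode {mode!r}")

    kmG = _km_survival(t, 1 - e)  # censoring distribution
    eps = 1e-9
    G_at_T = kmG.predict(np.maximum(t - eps, 0.0)).to_numpy(float)
    G_at_h = float(kmG.predict(horizon - eps))
    if G_at_h <= 0:
        raise ValueError("censoring survival reaches 0 before the horizon")
    w = np.zeros(len(t))
    w[event_by_h] = 1.0 / G_at_T[event_by_h]
    w[past_h & ~event_by_h] = 1.0 / G_at_h
    outcome = event_by_h.astype(float)
    return float(np.mean(w * (p - outcome) ** 2))


def harrell_cindex(
    scores,
    times,
    events,
    patient_ids=None,
    groups=None,
    chunk: int = 512,
    return_counts: bool = False,
):
    """Harrell's C over pairs of different individuals.

    A pair is comparable when the earlier observed time is an event time
    (under tied times, when exactly one of the two is an event).  Ties in
    score count 1/2.  ``patient_ids`` excludes pairs sharing an id;
    ``groups`` restricts comparisons to pairs in the same group (used for
    the age-adjusted C-index).
    """
    s = np.asarray(scores, float)
    t = np.asarray(times, float)
    e = np.asarray(events, int).astype(bool)
    n = len(s)
    pid = None if patient_ids is None else np.asarray(patient_ids)
    grp = None if groups is None else np.asarray(groups)

    concordant = 0.0
    comparable = 0
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        ti, tj = t[lo:hi, None], t[None, :]
        ei, ej = e[lo:hi, None], e[None, :]
        si, sj = s[lo:hi, None], s[None, :]
        upper = np.arange(lo, hi)[:, None] < np.arange(n)[None, :]
        ok = upper
        if pid is not None:
            ok = ok & (pid[lo:hi, None] != pid[None, :])
        if grp is not None:
            ok = ok & (grp[lo:hi, None] == grp[None, :])
        # i earlier event, j later (or censored later)
        a = ok & (ti < tj) & ei
        b = ok & (tj < ti) & ej
        tied = ok & (ti == tj) & (ei ^ ej)
        comparable += int(a.sum() + b.sum() + tied.sum())
        concordant += np.where(si > sj, 1.0, np.where(si == sj, 0.5, 0.0))[a].sum()
        concordant += np.where(sj > si, 1.0, np.where(si == sj, 0.5, 0.0))[b].sum()
        # under a tie in time the event member should have the higher score
        ev_hi = np.where(ei, si, sj)
        ev_lo = np.where(ei, sj, si)
        concordant += np.where(ev_hi > ev_lo, 1.0, np.where(ev_hi == ev_lo, 0.5, 0.0))[
            tied
        ].sum()
    if comparable == 0:
        raise ValueError("no comparable pairs")
    c = concordant / comparable
    return (c, concordant, comparable) if return_counts else c


def cindex_by_landmark_age(pred: pd.DataFrame) -> pd.DataFrame:
    """Age-adjusted C-index: comparisons restricted to same-landmark pairs.

    Returns per-landmark values with comparable-pair counts and an
    inverse-variance-style pooled value weighted by pair counts.
    """
    rows = []
    for s, grp in pred.groupby("s"):
        try:
            c, conc, comp = harrell_cindex(
                grp["risk10"],
                grp["time"],
                grp["event"],
                patient_ids=grp["patient_id"],
                return_counts=True,
            )
        except ValueError:
            continue
        rows.append({"s": s, "cindex": c, "n_pairs": comp, "n_rows": len(grp)})
    out = pd.DataFrame(rows)
    if len(out):
        out.attrs["pooled"] = float(
            np.average(out["cindex"], weights=out["n_pairs"])
        )
    return out


def calibration_deciles(
    predictions, times, events, horizon: float = 10.0, n_bins: int = 10
) -> pd.DataFrame:
    """Mean predicted vs KM-observed risk per decile of predicted risk."""
    p = np.asarray(predictions, float)
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    if len(p) < n_bins:
        raise ValueError(f"need at least {n_bins} rows")
    edges = np.unique(np.quantile(p, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 2:  # all predictions identical: one bin
        edges = np.array([edges[0], edges[0] + 1e-12])
    if len(edges) - 1 < n_bins:
        warnings.warn("tied predictions: merged empty calibration bins")
    bins = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        mask = bins == b
        if not mask.any():
            continue
        km = _km_survival(t[mask], e[mask])
        observed = 1.0 - float(km.predict(horizon))
        rows.append(
            {
                "decile": b + 1,
                "n": int(mask.sum()),
                "mean_predicted": float(p[mask].mean()),
                "observed": observed,
                "n_events": int(e[mask].sum()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ValidationReport:
    """Performance summary for one model variant."""

    variant: str
    brier: float
    brier_ci: tuple[float, float]
    brier_complete_case: float
    cindex: float
    cindex_ci: tuple[float, float]
    cindex_by_s: pd.DataFrame
    calibration: pd.DataFrame
    n_rows: int
    n_events: int
    predictions: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> dict:
        return {
            "variant": self.variant,
            "brier": self.brier,
            "brier_ci": list(self.brier_ci),
            "brier_complete_case": self.brier_complete_case,
            "cindex": self.cindex,
            "cindex_ci": list(self.cindex_ci),
            "n_rows": self.n_rows,
            "n_events": self.n_events,
        }


def _cluster_bootstrap_ci(pred: pd.DataFrame, stat_fn, n_boot: int, seed: int):
    """Percentile CI resampling patients (all their stacked rows together)."""
    pids = pred["patient_id"].unique()
    groups = dict(tuple(pred.groupby("patient_id")))
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_boot):
        draw = rng.choice(pids, size=len(pids), replace=True)
        boot = pd.concat([groups[p] for p in draw], ignore_index=True)
        # re-key resampled patients so duplicates act as distinct clusters
        sizes = [len(groups[p]) for p in draw]
        boot["patient_id"] = np.repeat(np.arange(len(draw)), sizes)
        try:
            vals.append(stat_fn(boot))
        except ValueError:
            continue
    if not vals:
        return (np.nan, np.nan)
    return tuple(np.quantile(vals, [0.025, 0.975]))


def validate_predictions(
    pred: pd.DataFrame,
    variant: str,
    horizon: float = 10.0,
    n_boot: int = 200,
    seed: int = 0,
) -> ValidationReport:
    """Compute the full metric suite on a pooled prediction table."""
    def _brier(df):
        return brier_score(df["risk10"], df["time"], df["event"], horizon)

    def _cindex(df):
        return harrell_cindex(
            df["risk10"], df["time"], df["event"], patient_ids=df["patient_id"]
        )

    brier = _brier(pred)
    cindex = _cindex(pred)
    brier_ci = _cluster_bootstrap_ci(pred, _brier, n_boot, seed)
    cindex_ci = _cluster_bootstrap_ci(pred, _cindex, n_boot, seed + 1)
    return ValidationReport(
        variant=variant,
        brier=brier,
        brier_ci=brier_ci,
        brier_complete_case=brier_score(
            pred["risk10"], pred["time"], pred["event"], horizon, mode="complete_case"
        ),
        cindex=cindex,
        cindex_ci=cindex_ci,
        cindex_by_s=cindex_by_landmark_age(pred),
        calibration=calibration_deciles(pred["risk10"], pred["time"], pred["event"], horizon),
        n_rows=len(pred),
        n_events=int(pred["event"].sum()),
        predictions=pred,
    )


# ---------------------------------------------------------------------------
# Cross-validation split by practice
# ---------------------------------------------------------------------------

def _subset_cohort(coh: cohort_mod.Cohort, practices) -> cohort_mod.Cohort:
    keep = coh.df["practice_id"].isin(practices)
    df = coh.df[keep].reset_index(drop=True)
    meas = coh.measurements[
        coh.measurements["patient_id"].isin(set(df["patient_id"]))
    ].reset_index(drop=True)
    return cohort_mod.Cohort(df=df, measurements=meas, flow=dict(coh.flow))


def _stage_tables(
    coh: cohort_mod.Cohort,
    std: cohort_mod.StandardizationParams,
    registry_like: pd.DataFrame,
    config: PipelineConfig,
    variants: list[str],
    stage1_params: dict | None = None,
):
    """Per-landmark covariate tables for each variant.

    When ``stage1_params`` is given (held-out fold), its fitted models are
    applied out-of-sample; otherwise models are fitted here and returned.
    """
    meas_std = std.standardize(coh.measurements, registry_like)
    fitted = {} if stage1_params is None else stage1_params
    tables: dict[str, list[pd.DataFrame]] = {v: [] for v in variants}
    need_stage1 = any(v in ("current_values", "age_interactions") for v in variants)
    for s in config.landmark_ages:
        lds = cohort_mod.build_landmark_dataset(
            s, coh, meas_std, horizon=config.horizon, landmark_grid=tuple(config.landmark_ages)
        )
        if not len(lds.outcomes):
            continue
        cv_table = None
        if need_stage1:
            parts = []
            for sex in ("male", "female"):
                if not (lds.outcomes["sex"] == sex).any():
                    continue
                key = (s, sex)
                if key not in fitted and stage1_params is not None:
                    raise RuntimeError(
                        f"no training-fold stage-1 fit for landmark {s}, sex {sex}; "
                        "cannot predict held-out persons without leaking"
                    )
                if key not in fitted:
                    spec = mlmm.MlmmSpec(
                        s=s,
                        sex=sex,
                        lookback_window=config.lookback_window,
                        visit_rate_covariate=config.visit_rate_adjust,
                    )
                    fitted[key] = mlmm.fit_mlmm(lds, sex, spec)
                parts.append(mlmm.estimate_current_values(fitted[key], lds))
            cv_table = pd.concat(parts) if parts else None
        for v in variants:
            if v == "basic":
                mv = None
            elif v in ("current_values", "age_interactions"):
                mv = cv_table
            elif v == "last_observed":
                mv = cohort_mod.last_observed(lds.history)
            else:
                mv = cohort_mod.cumulative_mean(lds.history)
            if v != "basic" and mv is not None:
                for m in MARKERS:
                    if m not in mv.columns:
                        mv[m] = np.nan
            tables[v].append(coxmodel.make_covariates(lds, mv, v))
    return tables, fitted


def cross_validate(
    registry: pd.DataFrame,
    measurements: pd.DataFrame,
    config: PipelineConfig,
    k: int | None = None,
) -> dict[str, ValidationReport]:
    """k-fold cross-validation split by general practice.

    Whole practices are never split across folds; standardization, stage-1
    and stage-2 parameters come from training practices only, and held-out
    persons receive out-of-sample BLUPs from the training stage-1 fits.
    Metrics are pooled over all held-out predictions.
    """
    k = k or config.cv_folds
    coh = cohort_mod.build_cohort(registry, measurements)
    practices = np.sort(coh.df["practice_id"].unique())
    if k > len(practices):
        raise ValueError(f"k={k} exceeds number of practices ({len(practices)})")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(practices)
    folds = [order[i::k] for i in range(k)]

    variants = list(config.variants)
    pooled: dict[str, list[pd.DataFrame]] = {v: [] for v in variants}
    for fold in folds:
        train = _subset_cohort(coh, np.setdiff1d(practices, fold))
        test = _subset_cohort(coh, fold)
        if not len(test.df):
            continue
        std = cohort_mod.fit_standardization(train.measurements, train.df)
        train_tabs, fitted = _stage_tables(train, std, train.df, config, variants)
        test_tabs, _ = _stage_tables(
            test, std, test.df, config, variants, stage1_params=fitted
        )
        for v in variants:
            stacked = coxmodel.stack_landmarks(train_tabs[v])
            fit = coxmodel.fit_cox(stacked, variant=v)
            test_stack = coxmodel.stack_landmarks(test_tabs[v])
            pooled[v].append(coxmodel.predict_10y_risk(fit, test_stack, config.horizon))

    reports = {}
    for v in variants:
        pred = pd.concat(pooled[v], ignore_index=True)
        reports[v] = validate_predictions(
            pred, v, horizon=config.horizon, n_boot=config.n_boot, seed=config.seed
        )
    return reports


def compare_models(
    reports: dict[str, ValidationReport],
    reference: str = "basic",
    n_boot: int = 200,
    seed: int = 0,
    horizon: float = 10.0,
) -> pd.DataFrame:
    """Delta C-index / Brier vs the reference, with cluster-bootstrap CIs.

    All reports must cover identical (patient, landmark) row sets;
    restricted-sample variants should be compared on the common rows.
    """
    if reference not in reports:
        raise ValueError(f"reference {reference!r} not among reports")
    ref = reports[reference].predictions.set_index(["patient_id", "s"]).sort_index()
    rows = []
    for name, rep in reports.items():
        if name == reference:
            continue
        other = rep.predictions.set_index(["patient_id", "s"]).sort_index()
        if not ref.index.equals(other.index):
            raise ValueError(
                f"row sets differ between {name!r} and reference {reference!r}"
            )
        merged = ref[["risk10", "time", "event"]].rename(
            columns={"risk10": "risk_ref"}
        )
        merged["risk_new"] = other["risk10"]
        merged = merged.reset_index()

        def _delta_c(df):
            kw = dict(patient_ids=df["patient_id"])
            return harrell_cindex(df["risk_new"], df["time"], df["event"], **kw) - \
                harrell_cindex(df["risk_ref"], df["time"], df["event"], **kw)

        def _delta_b(df):
            return brier_score(df["risk_new"], df["time"], df["event"], horizon) - \
                brier_score(df["risk_ref"], df["time"], df["event"], horizon)

        dc = _delta_c(merged)
        db = _delta_b(merged)
        dc_ci = _cluster_bootstrap_ci(merged, _delta_c, n_boot, seed)
        db_ci = _cluster_bootstrap_ci(merged, _delta_b, n_boot, seed + 1)
        rows.append(
            {
                "variant": name,
                "delta_cindex": dc,
                "delta_cindex_lo": dc_ci[0],
                "delta_cindex_hi": dc_ci[1],
                "delta_brier": db,
                "delta_brier_lo": db_ci[0],
                "delta_brier_hi": db_ci[1],
            }
        )
    return pd.DataFrame(rows)
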