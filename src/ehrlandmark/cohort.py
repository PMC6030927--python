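"""Cohort construction: study entry/exit rules, plausibility filters,
sex-specific standardization, landmark eligibility and per-landmark
datasets.

Conventions
-----------
* Ages are exact fractional years computed as (date - birth_date)/365.25 days.
* Study entry is the latest of: registration date + 6 months, the practice's
  acceptable-computer-usage date, its acceptable-mortality-reporting date,
  the 30th birthday, and the study start.  Exit is the earliest of: first
  CVD event, transfer out, death, and the study end.
* At a landmark age ``s`` a patient is eligible iff entry_age <= s <
  exit_age, with no CVD event and no statin prescription at or before ``s``.
  A measurement at exactly ``s`` belongs to the history; an event at exactly
  ``s`` makes the patient ineligible, guaranteeing positive follow-up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MARKERS, PLAUSIBLE_RANGE

_DAYS_PER_YEAR = 365.25

STUDY_START = "1997-01-01"
STUDY_END = "2016-01-18"

#: markers standardized to sex-specific z-scores
CONTINUOUS_MARKERS = ("sbp", "tchol", "hdlc")


def _age_at(dates: pd.Series, birth: pd.Series) -> pd.Series:
    return (pd.to_datetime(dates) - pd.to_datetime(birth)).dt.days / _DAYS_PER_YEAR


def incidence_rate(cases: int, person_years: float) -> float:
    """Crude incidence rate per 1,000 person-years, to one decimal."""
    if person_years <= 0:
        raise ValueError("person_years must be > 0")
    return round(1000.0 * cases / person_years, 1)


def apply_plausibility_filters(
    measurements: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove biologically implausible values (strict inequalities).

    SBP outside [60, 250] mm Hg, total cholesterol outside [1.75, 20] mmol/L
    and HDL-C outside [0.3, 3.1] mmol/L are dropped; boundary values are
    retained.  Returns the filtered table and per-marker removal counts.
    """
    unknown = set(measurements["marker"].unique()) - set(MARKERS)
    if unknown:
        bad = measurements.index[measurements["marker"].isin(unknown)][0]
        raise ValueError(
            f"unknown marker {measurements.loc[bad, 'marker']!r} at row {bad}"
        )
    keep = pd.Series(True, index=measurements.index)
    removed: dict[str, int] = {m: 0 for m in PLAUSIBLE_RANGE}
    for marker, (lo, hi) in PLAUSIBLE_RANGE.items():
        rows = measurements["marker"] == marker
        bad = rows & ((measurements["value"] < lo) | (measurements["value"] > hi))
        removed[marker] = int(bad.sum())
        keep &= ~bad
    return measurements.loc[keep].reset_index(drop=True), removed


@dataclass
class StandardizationParams:
    """Sex-specific mean/SD per continuous marker, in raw marker units."""

    params: dict[tuple[str, str], tuple[float, float]]

    def standardize(self, measurements: pd.DataFrame, registry: pd.DataFrame) -> pd.DataFrame:
        """Return a copy with a ``value_std`` column: z-scores for the
        continuous markers, smoking passed through unchanged."""
        sex_map = registry.set_index("patient_id")["sex"]
        out = measurements.copy()
        sexes = out["patient_id"].map(sex_map)
        out["value_std"] = out["value"].astype(float)
        for (sex, marker), (mu, sd) in self.params.items():
            rows = (sexes == sex) & (out["marker"] == marker)
            out.loc[rows, "value_std"] = (out.loc[rows, "value"] - mu) / sd
        return out

    def unstandardize(self, value_std: float, sex: str, marker: str) -> float:
        mu, sd = self.params[(sex, marker)]
        return value_std * sd + mu

    def to_json(self) -> str:
        return json.dumps(
            {f"{sex}:{marker}": [mu, sd] for (sex, marker), (mu, sd) in self.params.items()}
        )

    @classmethod
    def from_json(cls, text: str) -> "StandardizationParams":
        raw = json.loads(text)
        params = {}
        for key, (mu, sd) in raw.items():
            sex, marker = key.split(":")
            params[(sex, marker)] = (float(mu), float(sd))
        return cls(params)


def fit_standardization(
    measurements: pd.DataFrame, cohort_df: pd.DataFrame
) -> StandardizationParams:
    """Sex-specific means/SDs of the first post-entry measurement per person.

    Mirrors baseline-characteristics practice: one value per patient (their
    first measurement at or after study entry) so frequently measured
    patients do not dominate the scale.
    """
    entry = cohort_df.set_index("patient_id")["entry_age"]
    sex_map = cohort_df.set_index("patient_id")["sex"]
    meas = measurements[measurements["patient_id"].isin(entry.index)].copy()
    meas["entry_age"] = meas["patient_id"].map(entry)
    meas = meas[meas["age"] >= meas["entry_age"] - 1e-12]
    meas["sex"] = meas["patient_id"].map(sex_map)
    first = (
        meas.sort_values("age")
        .groupby(["patient_id", "marker"], as_index=False)
        .first()
    )
    params: dict[tuple[str, str], tuple[float, float]] = {}
    for (sex, marker), grp in first.groupby(["sex", "marker"]):
        if marker not in CONTINUOUS_MARKERS:
            continue
        if len(grp) < 2:
            raise ValueError(f"need >=2 observations to standardize {sex}/{marker}")
        mu = float(grp["value"].mean())
        sd = float(grp["value"].std(ddof=1))
        if sd <= 0:
            raise ValueError(f"zero standard deviation for {sex}/{marker}")
        params[(sex, marker)] = (mu, sd)
    return StandardizationParams(params)


# ---------------------------------------------------------------------------
# Study windows and cohort flow
# ---------------------------------------------------------------------------

def compute_study_windows(
    registry: pd.DataFrame,
    study_start: str = STUDY_START,
    study_end: str = STUDY_END,
) -> pd.DataFrame:
    """Apply the entry (latest-of) and exit (earliest-of) date rules.

    Returns one row per registry row with entry/exit dates and ages, the
    ages of first CVD/statin/diabetes/bp-medication codes, and an
    ``exclusion`` column ('' for retained patients).  Exclusion reasons, in
    order of precedence: missing_birth_date, unknown_sex, prior_cvd,
    prior_statin, entry_after_85, no_follow_up.
    """
    reg = registry.copy()
    start = pd.Timestamp(study_start)
    end = pd.Timestamp(study_end)
    birth = pd.to_datetime(reg["birth_date"])

    entry_candidates = pd.concat(
        [
            pd.to_datetime(reg["registration_date"]) + pd.DateOffset(months=6),
            pd.to_datetime(reg["acu_date"]),
            pd.to_datetime(reg["amr_date"]),
            birth + pd.DateOffset(years=30),
            pd.Series(start, index=reg.index),
        ],
        axis=1,
    )
    entry_date = entry_candidates.max(axis=1)
    exit_candidates = pd.concat(
        [
            pd.to_datetime(reg.get("first_cvd_event_date")),
            pd.to_datetime(reg.get("transfer_out_date")),
            pd.to_datetime(reg.get("death_date")),
            pd.Series(end, index=reg.index),
        ],
        axis=1,
    )
    exit_date = exit_candidates.min(axis=1)
    reg_date = pd.to_datetime(reg["registration_date"])
    for col in ("transfer_out_date", "death_date"):
        if col in reg.columns:
            bad = pd.to_datetime(reg[col]) < reg_date
            if bad.any():
                ids = list(reg.loc[bad, "patient_id"][:5])
                raise ValueError(f"{col} precedes registration for patients {ids}")

    out = pd.DataFrame(
        {
            "patient_id": reg["patient_id"],
            "practice_id": reg["practice_id"],
            "sex": reg["sex"],
            "entry_date": entry_date,
            "exit_date": exit_date,
            "entry_age": _age_at(entry_date, birth),
            "exit_age": _age_at(exit_date, birth),
            "cvd_age": _age_at(reg.get("first_cvd_event_date"), birth),
            "statin_age": _age_at(reg.get("first_statin_date"), birth),
            "diabetes_age": _age_at(reg.get("first_diabetes_date"), birth),
            "bp_med_age": _age_at(reg.get("first_bp_med_date"), birth),
        }
    )
    reasons = np.full(len(out), "", dtype=object)
    m = birth.isna().to_numpy()
    reasons[m] = "missing_birth_date"
    m2 = (~pd.Series(reasons).astype(bool)) & ~out["sex"].isin(["male", "female"])
    reasons[m2.to_numpy()] = "unknown_sex"
    free = pd.Series(reasons) == ""
    prior_cvd = free & (out["cvd_age"] <= out["entry_age"])
    reasons[prior_cvd.to_numpy()] = "prior_cvd"
    free = pd.Series(reasons) == ""
    prior_statin = free & (out["statin_age"] <= out["entry_age"])
    reasons[prior_statin.to_numpy()] = "prior_statin"
    free = pd.Series(reasons) == ""
    late = free & (out["entry_age"] > 85)
    reasons[late.to_numpy()] = "entry_after_85"
    free = pd.Series(reasons) == ""
    nofu = free & (out["entry_age"] >= out["exit_age"])
    reasons[nofu.to_numpy()] = "no_follow_up"
    out["exclusion"] = reasons
    return out


@dataclass
class Cohort:
    """Windows + filtered measurements + the cohort-flow log."""

    df: pd.DataFrame                    # retained patients with window ages
    measurements: pd.DataFrame          # filtered, age + bp_med columns
    flow: dict[str, int] = field(default_factory=dict)
    removed_measurements: dict[str, int] = field(default_factory=dict)


def build_cohort(
    registry: pd.DataFrame,
    measurements: pd.DataFrame,
    study_start: str = STUDY_START,
    study_end: str = STUDY_END,
) -> Cohort:
    """Windows, exclusions, plausibility filtering and the flow log.

    The final exclusion drops patients with no measurement of any marker
    between study entry and exit; everyone retained has at least one
    qualifying measurement, the condition under which the stage-1 model is
    estimable.
    """
    windows = compute_study_windows(registry, study_start, study_end)
    flow = {"target_population": len(windows)}
    for reason in windows["exclusion"].unique():
        if reason:
            flow[f"excluded_{reason}"] = int((windows["exclusion"] == reason).sum())
    kept = windows[windows["exclusion"] == ""].copy()

    meas = measurements.copy()
    if "age" not in meas.columns:
        birth = registry.set_index("patient_id")["birth_date"]
        meas["age"] = _age_at(meas["date"], meas["patient_id"].map(birth))
    meas, removed = apply_plausibility_filters(meas)

    # qualifying measurement: any marker, between entry and exit
    win = kept.set_index("patient_id")
    m_in = meas[meas["patient_id"].isin(win.index)].copy()
    entry = m_in["patient_id"].map(win["entry_age"])
    exit_ = m_in["patient_id"].map(win["exit_age"])
    qualifying = m_in[(m_in["age"] >= entry - 1e-12) & (m_in["age"] <= exit_ + 1e-12)]
    has_meas = set(qualifying["patient_id"].unique())
    n_drop = int((~kept["patient_id"].isin(has_meas)).sum())
    flow["excluded_no_qualifying_measurement"] = n_drop
    kept = kept[kept["patient_id"].isin(has_meas)].reset_index(drop=True)
    flow["study_sample"] = len(kept)

    meas = meas[meas["patient_id"].isin(set(kept["patient_id"]))].reset_index(drop=True)
    bp_age = kept.set_index("patient_id")["bp_med_age"]
    meas["bp_med"] = (
        meas["age"] >= meas["patient_id"].map(bp_age).fillna(np.inf)
    ).astype(int)
    return Cohort(df=kept, measurements=meas, flow=flow, removed_measurements=removed)


# ---------------------------------------------------------------------------
# Landmark datasets
# ---------------------------------------------------------------------------

def landmark_eligible(cohort_row, s: float) -> bool:
    """Registered at ``s``, no CVD event and no statin at or before ``s``."""
    if not (cohort_row.entry_age <= s < cohort_row.exit_age):
        return False
    cvd = getattr(cohort_row, "cvd_age", np.nan)
    if not np.isnan(cvd) and cvd <= s:
        return False
    statin = getattr(cohort_row, "statin_age", np.nan)
    if not np.isnan(statin) and statin <= s:
        return False
    return True


@dataclass
class LandmarkDataset:
    """One landmark age: outcome rows and the measurement history.

    ``outcomes`` has one row per eligible patient with follow-up time
    (years since ``s``, capped at the horizon), the event indicator within
    the horizon, and the carried-forward diabetes / bp-treatment flags at
    ``s``.  ``history`` is long-format with ``t = age - s`` in [30 - s, 0].
    """

    s: float
    outcomes: pd.DataFrame
    history: pd.DataFrame
    horizon: float = 10.0


def build_landmark_dataset(
    s: float,
    cohort: Cohort,
    measurements: pd.DataFrame | None = None,
    horizon: float = 10.0,
    landmark_grid: tuple[float, ...] | None = None,
) -> LandmarkDataset:
    """Assemble the landmark-age dataset at ``s``.

    ``measurements`` defaults to the cohort's filtered table and may be a
    standardized copy (with ``value_std``).  History is restricted to
    measurement ages in [30, s], both boundaries inclusive.
    """
    if landmark_grid is not None and s not in landmark_grid:
        raise ValueError(f"landmark age {s} not in configured grid {landmark_grid}")
    df = cohort.df
    elig = (
        (df["entry_age"] <= s)
        & (s < df["exit_age"])
        & ~(df["cvd_age"] <= s).fillna(False)
        & ~(df["statin_age"] <= s).fillna(False)
    )
    sub = df[elig].copy()
    time = np.minimum(sub["exit_age"] - s, horizon)
    event = ((sub["cvd_age"] - s) <= horizon).fillna(False) & sub["cvd_age"].notna()
    outcomes = pd.DataFrame(
        {
            "patient_id": sub["patient_id"].to_numpy(),
            "practice_id": sub["practice_id"].to_numpy(),
            "sex": sub["sex"].to_numpy(),
            "s": s,
            "time": time.to_numpy(),
            "event": event.to_numpy().astype(int),
            "diabetes": (sub["diabetes_age"] <= s).fillna(False).to_numpy().astype(int),
            "bp_med": (sub["bp_med_age"] <= s).fillna(False).to_numpy().astype(int),
        }
    )
    meas = cohort.measurements if measurements is None else measurements
    hist = meas[
        meas["patient_id"].isin(set(sub["patient_id"]))
        & (meas["age"] >= 30.0 - 1e-12)
        & (meas["age"] <= s + 1e-12)
    ].copy()
    hist["t"] = hist["age"] - s
    return LandmarkDataset(s=s, outcomes=outcomes, history=hist, horizon=horizon)


def last_observed(history: pd.DataFrame, value_col: str = "value_std") -> pd.DataFrame:
    """Latest value per (patient, marker); ties broken by record order."""
    h = history.sort_values(["patient_id", "marker", "age"], kind="stable")
    out = h.groupby(["patient_id", "marker"], as_index=False).last()
    return out.pivot(index="patient_id", columns="marker", values=value_col)


def cumulative_mean(history: pd.DataFrame, value_col: str = "value_std") -> pd.DataFrame:
    """Arithmetic mean of all history values per (patient, marker)."""
    out = history.groupby(["patient_id", "marker"], as_index=False)[value_col].mean()
    return out.pivot(index="patient_id", columns="marker", values=value_col)
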