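"""Synthetic EHR generator.

Emulates the structure of longitudinal primary-care records needed by the
two-stage landmark model: a patient registry (registration, transfer-out,
death, first-occurrence dates of diabetes codes, blood-pressure-lowering
and statin prescriptions, first CVD event) and a long-format measurement
table with sporadic per-marker visit processes.

Marker values follow the multivariate linear mixed model the first stage
assumes::

    y_ikj = beta0_k + beta1_k * age_ikj + gamma * bp_med(age) * [k == sbp]
            + b_ik + eps_ikj,

with person-level random intercepts ``b_i ~ MVN(0, G)`` shared across
markers and independent residuals ``eps ~ N(0, sigma2_k)``.  CVD event ages
are drawn from a proportional-hazards model with a sex-specific Gompertz
baseline acting on the *true* (error-free) current covariate values, so the
log hazard is piecewise linear in age and event times can be inverted
exactly segment by segment.

Reproducibility: each patient owns a deterministic substream derived from
``(seed, patient index)``, so increasing ``n_patients`` leaves earlier
patients' records bit-identical.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import MARKERS, RAW_SCALE, SynthConfig

_DAYS_PER_YEAR = 365.25


def _age_to_date(birth: pd.Timestamp, age: float) -> pd.Timestamp:
    return birth + pd.to_timedelta(int(round(age * _DAYS_PER_YEAR)), unit="D")


def _psd_factor(G: np.ndarray) -> np.ndarray:
    """Square root of a PSD matrix (eigen-based; tolerates singular G)."""
    vals, vecs = np.linalg.eigh(G)
    if vals.min() < -1e-10:
        raise ValueError("covariance matrix G is not positive semi-definite")
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def _exp_or_inf(rng: np.random.Generator, rate: float) -> float:
    return rng.exponential(1.0 / rate) if rate > 0 else np.inf


def generate_population(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate the registry skeleton, measurement table, and truth table.

    Returns ``(registry, measurements, truth)``.  The registry lacks CVD
    event dates until :func:`generate_outcomes` has run; ``truth`` carries
    the per-patient random intercepts and latent onset ages used both by
    the outcome model and by parameter-recovery tests.

    Measurement ages are drawn from homogeneous Poisson processes at the
    configured per-marker rates on [registration age, pre-event exit age];
    :func:`generate_outcomes` subsequently truncates them at the final exit.
    """
    config.validate()
    L = _psd_factor(config.true_G)
    study_end = pd.Timestamp(config.study_end)
    y0, y1 = config.birth_year_range
    birth_lo = pd.Timestamp(f"{y0}-01-01")
    birth_hi = pd.Timestamp(f"{y1}-12-31")
    r0, r1 = config.registration_year_range
    reg_lo = pd.Timestamp(f"{r0}-01-01")
    reg_days = (pd.Timestamp(f"{r1}-12-31") - reg_lo).days
    statin_era = pd.Timestamp(f"{config.statin_era_start}-01-01")

    # Practice-level quality dates from a dedicated substream.
    prng = np.random.default_rng(np.random.SeedSequence((config.seed, 1 << 20)))
    practice_ids = np.arange(config.n_practices)
    base = pd.Timestamp("1992-01-01")
    acu = [base + pd.to_timedelta(int(prng.integers(0, 6 * 365)), "D") for _ in practice_ids]
    amr = [base + pd.to_timedelta(int(prng.integers(0, 6 * 365)), "D") for _ in practice_ids]
    practices = pd.DataFrame(
        {"practice_id": practice_ids, "acu_date": acu, "amr_date": amr}
    )

    reg_rows, meas_rows, truth_rows = [], [], []
    for i in range(config.n_patients):
        ss = np.random.SeedSequence((config.seed, i))
        rng_pop, _rng_out = [np.random.default_rng(s) for s in ss.spawn(2)]

        practice = int(rng_pop.integers(config.n_practices))
        sex = "male" if rng_pop.random() < 0.5 else "female"

        # Registration date within the practices' electronic era; birth date
        # derived from a truncated-normal registration age (clamped to the
        # configured birth-year range).
        reg_date = reg_lo + pd.to_timedelta(int(rng_pop.integers(0, reg_days + 1)), "D")
        while True:
            reg_age = rng_pop.normal(config.registration_age_mean, config.registration_age_sd)
            if reg_age >= config.registration_age_min:
                break
        birth = reg_date - pd.to_timedelta(int(round(reg_age * _DAYS_PER_YEAR)), "D")
        birth = min(max(birth, birth_lo), birth_hi)
        reg_age = (reg_date - birth).days / _DAYS_PER_YEAR
        admin_age = (study_end - birth).days / _DAYS_PER_YEAR
        transfer_age = reg_age + _exp_or_inf(rng_pop, config.transfer_out_rate)
        death_age = reg_age + _exp_or_inf(rng_pop, config.death_rate)
        censor_exit_age = min(transfer_age, death_age, admin_age)

        # Condition / treatment clocks start at age 30; statin prescribing
        # additionally waits for the statin era.
        diabetes_age = 30.0 + _exp_or_inf(rng_pop, config.diabetes_rate)
        bp_med_age = 30.0 + _exp_or_inf(rng_pop, config.bp_med_rate)
        statin_start = max(30.0, (statin_era - birth).days / _DAYS_PER_YEAR)
        statin_age = statin_start + _exp_or_inf(rng_pop, config.statin_rate)

        b = L @ rng_pop.standard_normal(4)

        # Sporadic measurements on [registration, pre-event exit]:
        # independent per-marker Poisson processes, plus an optional shared
        # consultation process where one visit measures a random subset of
        # markers (correlated missingness).
        start = reg_age
        span = max(censor_exit_age - start, 0.0)
        shared_ages = np.array([])
        if config.shared_consultation_rate > 0 and span > 0:
            n_s = rng_pop.poisson(config.shared_consultation_rate * span)
            shared_ages = start + rng_pop.random(n_s) * span
        for k, marker in enumerate(MARKERS):
            rate = config.visit_rate_per_marker.get(marker, 0.0)
            n_k = rng_pop.poisson(rate * span) if rate > 0 and span > 0 else 0
            ages = start + rng_pop.random(n_k) * span if n_k else np.array([])
            if len(shared_ages):
                measured = rng_pop.random(len(shared_ages)) < 0.5
                ages = np.concatenate([ages, shared_ages[measured]])
            if len(ages) == 0:
                continue
            ages = np.sort(ages)
            beta0, beta1 = config.true_fixed_effects[marker]
            latent = beta0 + beta1 * ages + b[k]
            if marker == "sbp":
                latent = latent + config.bp_med_effect_on_sbp * (ages >= bp_med_age)
            eps = rng_pop.normal(0.0, np.sqrt(config.true_sigma2[marker]), len(ages))
            if marker == "smoking" and config.smoking_mode == "bernoulli-threshold":
                values = (latent + eps > 0.5).astype(float)
            else:
                loc, scale = RAW_SCALE[marker]
                values = loc + scale * (latent + eps)
            for age, val in zip(ages, values):
                meas_rows.append((i, marker, age, float(val)))

        reg_rows.append(
            {
                "patient_id": i,
                "practice_id": practice,
                "sex": sex,
                "birth_date": birth,
                "registration_date": _age_to_date(birth, reg_age),
                "transfer_out_date": (
                    _age_to_date(birth, transfer_age)
                    if transfer_age <= min(death_age, admin_age)
                    else pd.NaT
                ),
                "death_date": (
                    _age_to_date(birth, death_age)
                    if death_age <= min(transfer_age, admin_age)
                    else pd.NaT
                ),
                "first_cvd_event_date": pd.NaT,
                "first_diabetes_date": (
                    _age_to_date(birth, diabetes_age) if diabetes_age <= censor_exit_age else pd.NaT
                ),
                "first_bp_med_date": (
                    _age_to_date(birth, bp_med_age) if bp_med_age <= censor_exit_age else pd.NaT
                ),
                "first_statin_date": (
                    _age_to_date(birth, statin_age) if statin_age <= censor_exit_age else pd.NaT
                ),
            }
        )
        truth_rows.append(
            {
                "patient_id": i,
                "sex": sex,
                "birth_date": birth,
                "registration_age": reg_age,
                "admin_age": admin_age,
                "censor_exit_age": censor_exit_age,
                "diabetes_age": diabetes_age,
                "bp_med_age": bp_med_age,
                "statin_age": statin_age,
                **{f"b_{m}": b[k] for k, m in enumerate(MARKERS)},
            }
        )

    registry = pd.DataFrame(reg_rows).merge(practices, on="practice_id", how="left")
    measurements = pd.DataFrame(
        meas_rows, columns=["patient_id", "marker", "age", "value"]
    )
    truth = pd.DataFrame(truth_rows)
    if len(measurements):
        birth_map = registry.set_index("patient_id")["birth_date"]
        measurements["date"] = [
            _age_to_date(birth_map[pid], age)
            for pid, age in zip(measurements["patient_id"], measurements["age"])
        ]
    else:
        measurements["date"] = pd.Series([], dtype="datetime64[ns]")
    return registry, measurements, truth


def _event_age_piecewise_gompertz(
    rng: np.random.Generator,
    c_segments: list[tuple[float, float, float]],
    d: float,
) -> float:
    """Invert one exponential draw through a piecewise log-linear hazard.

    ``c_segments`` is a list of (a0, a1, c) with hazard exp(c + d*a) on
    [a0, a1).  Returns the event age, or inf if no event before the end.
    """
    u = rng.exponential()
    for a0, a1, c in c_segments:
        if a1 <= a0:
            continue
        if abs(d) < 1e-12:
            lam = np.exp(c)
            seg = lam * (a1 - a0)
            if u < seg:
                return a0 + u / lam
        else:
            e0 = np.exp(d * a0)
            seg = np.exp(c) / d * (np.exp(d * a1) - e0)
            if u < seg:
                return np.log(e0 + d * u * np.exp(-c)) / d
        u -= seg
    return np.inf


def generate_outcomes(
    registry: pd.DataFrame, truth: pd.DataFrame, config: SynthConfig
) -> pd.DataFrame:
    """Draw first-CVD-event ages and finalize the registry.

    The hazard at age ``a`` is ``lambda0_sex(a) * exp(theta' x_true(a))``
    where ``x_true`` holds the error-free current marker values (including
    the treatment shift on SBP) and the carried-forward diabetes and
    bp-medication flags.  Risk accrues from age 30; events occurring after
    the transfer/death/administrative exit are censored.
    """
    config.validate()
    theta = config.true_log_hazard_ratios
    rho = config.baseline_hazard_log_slope
    d = rho + sum(
        theta.get(m, 0.0) * config.true_fixed_effects[m][1] for m in MARKERS
    )
    out = registry.copy()
    event_ages = np.full(len(truth), np.inf)
    for idx, row in enumerate(truth.itertuples(index=False)):
        ss = np.random.SeedSequence((config.seed, int(row.patient_id)))
        rng_out = np.random.default_rng(ss.spawn(2)[1])
        lam30 = config.baseline_hazard_rate_at_30[row.sex]
        if lam30 <= 0:
            continue
        c0 = (
            np.log(lam30)
            - 30.0 * rho
            + sum(
                theta.get(m, 0.0)
                * (config.true_fixed_effects[m][0] + getattr(row, f"b_{m}"))
                for m in MARKERS
            )
        )
        end = row.censor_exit_age
        if end <= 30.0:
            continue
        # Breakpoints where the carried-forward flags switch on.
        bps = sorted(
            a for a in (row.diabetes_age, row.bp_med_age) if 30.0 < a < end
        )
        edges = [30.0] + bps + [end]
        segments = []
        for a0, a1 in zip(edges, edges[1:]):
            c = c0
            if row.diabetes_age <= a0:
                c += theta.get("diabetes", 0.0)
            if row.bp_med_age <= a0:
                c += theta.get("bp_med", 0.0) + theta.get("sbp", 0.0) * config.bp_med_effect_on_sbp
            segments.append((a0, a1, c))
        event_ages[idx] = _event_age_piecewise_gompertz(rng_out, segments, d)

    birth = truth["birth_date"].to_numpy()
    has_event = np.isfinite(event_ages)
    dates = [
        _age_to_date(pd.Timestamp(b), a) if ok else pd.NaT
        for b, a, ok in zip(birth, event_ages, has_event)
    ]
    ev = pd.DataFrame(
        {"patient_id": truth["patient_id"], "first_cvd_event_date": dates}
    )
    out = out.drop(columns=["first_cvd_event_date"]).merge(ev, on="patient_id", how="left")
    return out


def simulate(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full simulation: population, outcomes, and exit-consistent tables.

    Measurements recorded after the final exit (CVD event, transfer, death
    or administrative end) are dropped so the tables satisfy the
    registry/measurement ordering invariants.
    """
    registry, measurements, truth = generate_population(config)
    registry = generate_outcomes(registry, truth, config)

    exit_age = _final_exit_age(registry)
    if len(measurements):
        keep = measurements["age"] <= measurements["patient_id"].map(exit_age) + 1e-12
        measurements = measurements.loc[keep].reset_index(drop=True)
    return registry, measurements, truth


def _final_exit_age(registry: pd.DataFrame) -> pd.Series:
    """Age at the earliest of event/transfer/death dates (admin end included
    implicitly because generation stops there)."""
    exit_date = registry[
        ["first_cvd_event_date", "transfer_out_date", "death_date"]
    ].min(axis=1)
    ages = (exit_date - registry["birth_date"]).dt.days / _DAYS_PER_YEAR
    return pd.Series(ages.fillna(np.inf).to_numpy(), index=registry["patient_id"].to_numpy())


def write_tables(registry: pd.DataFrame, measurements: pd.DataFrame, outdir) -> None:
    """Write the two delimited tables with ISO-8601 dates."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reg = registry.copy()
    for col in reg.columns:
        if pd.api.types.is_datetime64_any_dtype(reg[col]):
            reg[col] = reg[col].dt.strftime("%Y-%m-%d")
    meas = measurements.copy()
    meas["date"] = meas["date"].dt.strftime("%Y-%m-%d")
    reg.to_csv(outdir / "registry.csv", index=False)
    meas[["patient_id", "marker", "date", "value"]].to_csv(
        outdir / "measurements.csv", index=False
    )
    (outdir / "data_dictionary.md").write_text(_DATA_DICTIONARY)


_DATA_DICTIONARY = """\
# Data dictionary

## registry.csv (one row per patient)

| column | description |
| --- | --- |
| patient_id | integer patient identifier |
| practice_id | integer general-practice identifier |
| sex | 'male' or 'female' |
| birth_date | ISO-8601 date |
| registration_date | date of registration with the practice |
| acu_date | practice's acceptable-computer-usage date |
| amr_date | practice's acceptable-mortality-reporting date |
| transfer_out_date | date of transfer out of the practice (empty if none) |
| death_date | date of death (empty if none) |
| first_cvd_event_date | date of first CVD event (empty if none) |
| first_diabetes_date | date of first diabetes code (empty if none) |
| first_bp_med_date | first blood-pressure-lowering prescription (empty if none) |
| first_statin_date | first statin prescription (empty if none) |

## measurements.csv (long format, one row per measurement)

| column | description |
| --- | --- |
| patient_id | integer patient identifier |
| marker | one of smoking, sbp, tchol, hdlc |
| date | ISO-8601 measurement date |
| value | raw value (smoking unitless; sbp mm Hg; tchol/hdlc mmol/L) |
"""
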