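"""End-to-end orchestration: simulate -> cohort -> stage 1 -> stage 2 ->
predict -> validate, with plain-text artifacts stamped by config hash and
seed so any stage can be inspected or rerun independently."""

from __future__ import annotations

import hashlib
import json
import pathlib
import time

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import coxmodel, mlmm, synthetic, validation
from .config import PipelineConfig, SynthConfig


def _hash_config(*objs) -> str:
    text = json.dumps([getattr(o, "to_dict", lambda: vars(o))() for o in objs], default=str, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def run_pipeline(
    synth_config: SynthConfig,
    config: PipelineConfig,
    outdir,
    registry: pd.DataFrame | None = None,
    measurements: pd.DataFrame | None = None,
) -> dict:
    """Run the full pipeline, writing artifacts under ``outdir``.

    When ``registry``/``measurements`` are not supplied they are simulated
    from ``synth_config``.  Returns a dictionary with the cohort flow, the
    apparent (training-data) fits, cross-validated reports and the model
    comparison table.
    """
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config_hash": _hash_config(synth_config, config), "seed": config.seed}
    t0 = time.time()

    stage = "simulate"
    try:
        if registry is None:
            registry, measurements, _ = synthetic.simulate(synth_config)
            synthetic.write_tables(registry, measurements, out / "data")
        log["n_patients_input"] = len(registry)

        stage = "build-cohort"
        coh = cohort_mod.build_cohort(registry, measurements)
        log["cohort_flow"] = coh.flow
        log["removed_measurements"] = coh.removed_measurements

        stage = "fit-stage1"
        std = cohort_mod.fit_standardization(coh.measurements, coh.df)
        (out / "stage1").mkdir(exist_ok=True)
        (out / "stage1" / "standardization.json").write_text(std.to_json())
        variants = list(config.variants)
        tables, fitted = validation._stage_tables(coh, std, coh.df, config, variants)
        for (s, sex), params in fitted.items():
            (out / "stage1" / f"mlmm_s{int(s)}_{sex}.json").write_text(params.to_json())
        log["stage1_converged"] = {
            f"{s}_{sex}": p.converged for (s, sex), p in fitted.items()
        }

        stage = "fit-stage2"
        apparent = {}
        (out / "stage2").mkdir(exist_ok=True)
        for v in variants:
            stacked = coxmodel.stack_landmarks(tables[v])
            fit = coxmodel.fit_cox(stacked, variant=v)
            apparent[v] = fit
            pred = coxmodel.predict_10y_risk(fit, stacked, config.horizon)
            pred.to_csv(out / "stage2" / f"predictions_{v}.csv", index=False)
            artifact = {
                "variant": v,
                "theta": fit.theta.to_dict(),
                "robust_se": fit.robust_se().to_dict(),
                "baseline_cumhaz_at_horizon": {
                    sx: fit.baseline_cumhaz(sx, config.horizon) for sx in fit.baseline
                },
                "n_rows": fit.n_rows,
                "n_events": fit.n_events,
            }
            (out / "stage2" / f"cox_{v}.json").write_text(
                json.dumps(artifact, indent=1)
            )

        stage = "validate"
        reports = validation.cross_validate(registry, measurements, config)
        for v, rep in reports.items():
            rep.calibration.to_csv(out / f"calibration_{v}.csv", index=False)
            rep.cindex_by_s.to_csv(out / f"cindex_by_age_{v}.csv", index=False)
            rep.predictions.to_csv(out / f"cv_predictions_{v}.csv", index=False)
        log["cv_reports"] = {v: rep.summary() for v, rep in reports.items()}

        comparison = None
        comparable = [
            v for v in variants
            if v != "basic" and v in ("current_values", "age_interactions")
        ]
        if "basic" in variants and comparable:
            comparison = validation.compare_models(
                {v: reports[v] for v in ["basic"] + comparable},
                reference="basic",
                n_boot=config.n_boot,
                seed=config.seed,
                horizon=config.horizon,
            )
            comparison.to_csv(out / "model_comparison.csv", index=False)
            log["comparison"] = comparison.to_dict(orient="records")
    except Exception as err:
        log["failed_stage"] = stage
        (out / "run_log.json").write_text(json.dumps(log, indent=1, default=_jsonify))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    log["runtime_s"] = round(time.time() - t0, 2)
    (out / "run_log.json").write_text(json.dumps(log, indent=1, default=_jsonify))
    return {
        "cohort": coh,
        "standardization": std,
        "stage1": fitted,
        "stage2": apparent,
        "cv_reports": reports,
        "comparison": comparison,
        "log": log,
    }


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
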