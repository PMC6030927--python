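"""Configuration objects for the synthetic-EHR generator and the pipeline.

All randomness in the package flows from a single integer seed.  Generator
parameters mirror the quantities of the two-stage model: per-marker fixed
intercepts/slopes ``beta0, beta1`` on the age scale, the treatment effect
``gamma`` of blood-pressure-lowering medication on SBP, the 4x4 covariance
``G`` of the correlated person-level random intercepts, residual variances
``sigma2``, and per-covariate log hazard ratios driving the event model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

MARKERS = ("smoking", "sbp", "tchol", "hdlc")

#: Plausibility limits (raw marker units); values outside are removed.
PLAUSIBLE_RANGE = {
    "sbp": (60.0, 250.0),      # mm Hg
    "tchol": (1.75, 20.0),     # mmol/L
    "hdlc": (0.3, 3.1),        # mmol/L
}

#: Raw-unit location/scale used to map latent standardized trajectories to
#: measurement units (population means/SDs of first post-entry measurements).
RAW_SCALE = {
    "smoking": (0.0, 1.0),
    "sbp": (134.8, 21.0),
    "tchol": (5.5, 1.1),
    "hdlc": (1.4, 0.4),
}

DEFAULT_LANDMARK_AGES = tuple(range(40, 90, 5))  # 40, 45, ..., 85


def _default_G() -> np.ndarray:
    # Between-person covariance of random intercepts on the standardized
    # scale; moderate positive SBP-cholesterol correlation, HDL-C inversely
    # related to the atherogenic markers.
    sd = np.sqrt(np.array([0.15, 0.50, 0.50, 0.60]))
    corr = np.array(
        [
            [1.00, 0.05, 0.10, -0.15],
            [0.05, 1.00, 0.20, -0.10],
            [0.10, 0.20, 1.00, -0.20],
            [-0.15, -0.10, -0.20, 1.00],
        ]
    )
    return corr * np.outer(sd, sd)


@dataclass
class SynthConfig:
    """Parameters of the synthetic EHR generator.

    Visit rates default to the reciprocal of the mean inter-measurement gaps
    observed in UK primary care (about 1.1 y for smoking status, 0.5 y for
    SBP, 1.1 y for total cholesterol and 1.2 y for HDL-C).  Baseline hazard
    is Gompertz per sex; the defaults yield a roughly 7% 10-year event
    fraction with crude incidence rising steeply with age.
    """

    seed: int = 0
    n_patients: int = 2000
    n_practices: int = 10
    birth_year_range: tuple[int, int] = (1930, 1975)

    # Registration / exit process: registration dates fall in the practices'
    # electronic era; registration age is truncated normal, with the birth
    # date derived from the two (clamped to birth_year_range).
    registration_year_range: tuple[int, int] = (1987, 2010)
    registration_age_mean: float = 45.0
    registration_age_sd: float = 14.0
    registration_age_min: float = 18.0
    transfer_out_rate: float = 0.045    # per year since registration
    death_rate: float = 0.004           # per year since registration
    study_start: str = "1997-01-01"
    study_end: str = "2016-01-18"

    # Sporadic visit processes (independent homogeneous Poisson per marker)
    visit_rate_per_marker: dict[str, float] = field(
        default_factory=lambda: {
            "smoking": 1.0 / 1.1,
            "sbp": 2.0,
            "tchol": 1.0 / 1.1,
            "hdlc": 1.0 / 1.2,
        }
    )
    shared_consultation_rate: float = 0.0  # optional shared visit process

    # Latent trajectory model (standardized scale): value = beta0 + beta1*age
    # + gamma*bp_med (SBP only) + b_i + eps
    true_fixed_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "smoking": (0.50, -0.004),
            "sbp": (-1.25, 0.025),
            "tchol": (-0.90, 0.018),
            "hdlc": (0.25, -0.005),
        }
    )
    bp_med_effect_on_sbp: float = -0.40
    true_G: np.ndarray = field(default_factory=_default_G)
    true_sigma2: dict[str, float] = field(
        default_factory=lambda: {"smoking": 0.05, "sbp": 0.50, "tchol": 0.40, "hdlc": 0.30}
    )
    smoking_mode: str = "linear-gaussian"  # or "bernoulli-threshold"

    # Condition / treatment initiation (exponential clocks from age 30;
    # statins only from the statin prescribing era onwards)
    diabetes_rate: float = 0.011
    bp_med_rate: float = 0.030
    statin_rate: float = 0.016
    statin_era_start: int = 1995

    # Event model: Gompertz baseline per sex + proportional hazards on the
    # true (error-free) current covariate values
    baseline_hazard_rate_at_30: dict[str, float] = field(
        default_factory=lambda: {"male": 0.00045, "female": 0.0003}
    )
    baseline_hazard_log_slope: float = 0.062  # per year of age
    # Log hazard ratios per standardized unit (flags: per unit), in line
    # with cardiovascular epidemiology: smoking HR ~2, SBP ~1.6 per SD
    # (21 mm Hg), total cholesterol ~1.3 per SD, HDL-C ~0.7 per SD,
    # diabetes ~1.9.
    true_log_hazard_ratios: dict[str, float] = field(
        default_factory=lambda: {
            "smoking": 0.70,
            "sbp": 0.48,
            "tchol": 0.27,
            "hdlc": -0.38,
            "diabetes": 0.65,
            "bp_med": 0.15,
        }
    )

    def __post_init__(self) -> None:
        self.true_G = np.asarray(self.true_G, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_practices < 1:
            raise ValueError("n_practices must be >= 1")
        for name, r in self.visit_rate_per_marker.items():
            if r < 0:
                raise ValueError(f"visit rate for {name} must be >= 0")
        for name, r in [
            ("diabetes_rate", self.diabetes_rate),
            ("bp_med_rate", self.bp_med_rate),
            ("statin_rate", self.statin_rate),
            ("transfer_out_rate", self.transfer_out_rate),
            ("death_rate", self.death_rate),
        ]:
            if r < 0:
                raise ValueError(f"{name} must be >= 0")
        G = self.true_G
        if G.shape != (4, 4) or not np.allclose(G, G.T, atol=1e-10):
            raise ValueError("true_G must be a symmetric 4x4 matrix")
        eig = np.linalg.eigvalsh(G)
        if eig.min() < -1e-10:
            raise ValueError("true_G must be positive semi-definite")
        for k, v in self.true_sigma2.items():
            if v <= 0:
                raise ValueError(f"true_sigma2[{k}] must be > 0")
        if self.smoking_mode not in ("linear-gaussian", "bernoulli-threshold"):
            raise ValueError(f"unknown smoking_mode: {self.smoking_mode}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_G"] = np.asarray(self.true_G).tolist()
        return d


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings: landmark grid, variants, CV, seed."""

    seed: int = 0
    landmark_ages: Sequence[int] = DEFAULT_LANDMARK_AGES
    variants: Sequence[str] = ("basic", "current_values")
    lookback_window: float = float("inf")
    visit_rate_adjust: bool = False
    cv_folds: int = 10
    n_boot: int = 200
    horizon: float = 10.0

    def __post_init__(self) -> None:
        ages = list(self.landmark_ages)
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("landmark_ages must be strictly increasing")
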