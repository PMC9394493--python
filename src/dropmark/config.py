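"""Configuration objects for the synthetic cohort generator and the pipeline.

Defaults reproduce the study conditions of the source cohort: 744 male
recruits per cohort in a 24-week programme, baseline anthropometrics and
fitness-test distributions matching the published summary table, true
covariate effects equal to the published log hazard ratios, and a weekly
base hazard calibrated so the expected total dropout is 54.8% with 22% of
dropouts falling in the first four weeks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .design import CoefficientSet, LIKERT_ITEMS

__all__ = [
    "CovariateSpec",
    "MissingnessConfig",
    "GeneratorConfig",
    "PipelineConfig",
    "DEFAULT_TRUE_HAZARD_RATIOS",
    "default_weekly_base_hazard",
]

#: Published multivariable hazard ratios used as the generator's true effects.
DEFAULT_TRUE_HAZARD_RATIOS: dict[str, float] = {
    "height_m": 0.674,
    "body_mass_kg": 0.957,
    "age": 0.967,
    "education_1": 0.913,
    "education_2": 0.675,
    "body_fat_pct": 1.034,
    "cooper_km": 0.157,
    "pushups_per10": 0.984,
    "situps_per10": 0.999,
    "health": 0.984,
    "motivated": 0.655,
    "soreness": 1.053,
    "sleep": 1.048,
    "physfit": 0.792,
    "pain": 0.673,
    "health_x_landmark": 0.992,
    "motivated_x_landmark": 1.018,
    "soreness_x_landmark": 0.998,
    "sleep_x_landmark": 1.004,
    "physfit_x_landmark": 1.007,
    "pain_x_landmark": 0.999,
}

# Weekly base hazard h0_w = scale * decay**(w-1) for the reference subject.
# The two free parameters were calibrated once by root finding on the
# expected-dropout equations (see simulate.calibrate_base_hazard and
# analysis/01_calibrate_generator.py) to hit 54.8% total dropout with 22%
# of dropouts inside the first four weeks.
DEFAULT_BASE_HAZARD_SCALE = 0.0641584
DEFAULT_BASE_HAZARD_DECAY = 1.01853


def default_weekly_base_hazard(duration_weeks: int = 24,
                               scale: float = DEFAULT_BASE_HAZARD_SCALE,
                               decay: float = DEFAULT_BASE_HAZARD_DECAY) -> np.ndarray:
    """Geometric weekly base hazard vector (integrated hazard per week)."""
    w = np.arange(duration_weeks, dtype=float)
    return scale * decay**w


@dataclass(frozen=True)
class CovariateSpec:
    """Target mean/SD and eligibility bounds of one continuous baseline covariate.

    ``mean`` is the *realized* (post-truncation) target; the sampler solves
    for the pre-truncation location so the generated mean matches it.
    """

    mean: float
    sd: float
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"sd must be positive, got {self.sd}")
        if not self.lower < self.upper:
            raise ValueError("lower bound must be below upper bound")
        if not (self.lower <= self.mean <= self.upper) and np.isfinite(self.lower):
            raise ValueError(
                f"target mean {self.mean} outside eligibility bounds "
                f"[{self.lower}, {self.upper}]: truncation infeasible"
            )


def _default_baseline_specs() -> dict[str, CovariateSpec]:
    # Published cohort: age 21 +/- 2.4 y within the 17.5-27.9 y employment
    # window; height 1.81 +/- 0.064 m (floor 1.65 m); body mass 77.9 +/- 7.9 kg
    # (floor 65 kg); body fat 13.6 +/- 3.1%; Cooper 2.87 +/- 1.58 km (entry
    # minimum 2.7 km); push-ups 54.2 +/- 11.5 and sit-ups 55.0 +/- 7.5
    # (entry minimum 30 each).
    return {
        "age": CovariateSpec(21.0, 2.4, 17.5, 27.9),
        "height_m": CovariateSpec(1.81, 0.064, 1.65),
        "body_mass_kg": CovariateSpec(77.9, 7.9, 65.0),
        "body_fat_pct": CovariateSpec(13.6, 3.1, 3.0, 40.0),
        "cooper_km": CovariateSpec(2.87, 1.58, 2.7),
        "pushups": CovariateSpec(54.2, 11.5, 30.0),
        "situps": CovariateSpec(55.0, 7.5, 30.0),
    }


def _default_item_means() -> dict[str, float]:
    # Recruits self-report on the high end of the 10-point scale; the mental
    # fitness item is near-ceiling with almost no spread, which is what makes
    # it screenable (near-zero variance) in the pipeline.
    return {
        "health": 7.5,
        "motivated": 7.5,
        "soreness": 6.5,
        "sleep": 7.0,
        "mentalfit": 9.3,
        "physfit": 7.5,
    }


def _default_item_intercept_sds() -> dict[str, float]:
    return {
        "health": 1.0,
        "motivated": 1.0,
        "soreness": 1.0,
        "sleep": 1.0,
        "mentalfit": 0.3,
        "physfit": 1.0,
    }


def _default_item_noise_sds() -> dict[str, float]:
    return {
        "health": 1.0,
        "motivated": 1.0,
        "soreness": 1.0,
        "sleep": 1.0,
        "mentalfit": 0.3,
        "physfit": 1.0,
    }


@dataclass(frozen=True)
class MissingnessConfig:
    """Probabilities governing the degradation of a complete simulated cohort.

    Defaults match the published cohort: 8% of recruits with at least one
    missing baseline measurement, 4% left-truncated weekly status, 1.4%
    week-1 dropouts with no status observations, and 61% of the mental
    fitness item missing not at random (missingness increasing as the latent
    value falls).
    """

    p_missing_baseline: float = 0.08
    p_left_truncated: float = 0.04
    p_week1_dropout_no_obs: float = 0.014
    p_mnar_mentalfit: float = 0.61
    mnar_strength: float = 1.0
    p_skip_week: float = 0.05  # survey-level nonresponse (weeks >= 2), filled by LOCF downstream
    max_truncated_weeks: int = 3

    def __post_init__(self) -> None:
        for name in ("p_missing_baseline", "p_left_truncated",
                     "p_week1_dropout_no_obs", "p_mnar_mentalfit", "p_skip_week"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.mnar_strength < 0:
            raise ValueError("mnar_strength must be non-negative")
        if self.max_truncated_weeks < 1:
            raise ValueError("max_truncated_weeks must be at least 1")

    @classmethod
    def none(cls) -> "MissingnessConfig":
        """A configuration that leaves the cohort untouched."""
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class GeneratorConfig:
    n_recruits: int = 744
    duration_weeks: int = 24
    baseline_specs: Mapping[str, CovariateSpec] = field(default_factory=_default_baseline_specs)
    education_probs: tuple[float, float, float] = (0.25, 0.17, 0.58)  # level_1, level_2, unknown
    item_means: Mapping[str, float] = field(default_factory=_default_item_means)
    item_intercept_sds: Mapping[str, float] = field(default_factory=_default_item_intercept_sds)
    item_noise_sds: Mapping[str, float] = field(default_factory=_default_item_noise_sds)
    likert_ar_coef: float = 0.7
    true_coefficients: CoefficientSet = field(
        default_factory=lambda: CoefficientSet.from_hazard_ratios(DEFAULT_TRUE_HAZARD_RATIOS)
    )
    weekly_base_hazard: tuple[float, ...] = field(
        default_factory=lambda: tuple(default_weekly_base_hazard())
    )
    injury_weekly_prob: float = 0.015
    pain_reason_multiplier: float = 3.0
    # published reason frequencies 137:240:27 (injury, individual request,
    # other); they sum to 404 of 408 dropouts, so the mixture is normalized
    reason_mixture: tuple[float, float, float] = (137 / 404, 240 / 404, 27 / 404)
    landmark_coding: str = "s_minus_1"
    exit_survey_missing_prob: float = 0.25
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_recruits < 0:
            raise ValueError("n_recruits must be non-negative")
        if self.duration_weeks < 2:
            raise ValueError("duration_weeks must be at least 2")
        if abs(sum(self.education_probs) - 1.0) > 1e-12:
            raise ValueError("education_probs must sum to 1")
        if abs(sum(self.reason_mixture) - 1.0) > 1e-12:
            raise ValueError("reason_mixture must sum to 1")
        if not 0.0 < self.likert_ar_coef < 1.0:
            raise ValueError("likert_ar_coef must lie in (0, 1)")
        for item in LIKERT_ITEMS:
            if self.item_noise_sds[item] < 0 or self.item_intercept_sds[item] < 0:
                raise ValueError("Likert noise/intercept SDs must be non-negative")
        h = np.asarray(self.weekly_base_hazard, dtype=float)
        if len(h) != self.duration_weeks:
            raise ValueError(
                f"weekly_base_hazard has length {len(h)}, expected {self.duration_weeks}"
            )
        if (h < 0).any():
            raise ValueError("weekly_base_hazard must be non-negative")
        if not 0.0 <= self.injury_weekly_prob <= 1.0:
            raise ValueError("injury_weekly_prob must lie in [0, 1]")
        if self.landmark_coding not in ("s", "s_minus_1"):
            raise ValueError("landmark_coding must be 's' or 's_minus_1'")

    @property
    def duration_days(self) -> int:
        return 7 * self.duration_weeks

    def base_hazard_array(self) -> np.ndarray:
        return np.asarray(self.weekly_base_hazard, dtype=float)

    def replace(self, **changes) -> "GeneratorConfig":
        from dataclasses import replace as _replace

        return _replace(self, **changes)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end settings: simulate -> preprocess -> stack -> fit -> evaluate."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    apply_missingness: bool = True
    max_missing_frac: float = 0.5
    min_variance: float = 1e-3
    pain_carry: str = "absorbing"
    landmark_coding: str = "s_minus_1"
    ties_method: str = "breslow"
    variance_method: str = "model"
    eval_weeks: tuple[int, ...] = (1, 4, 12)
    roc_window_days: int = 7
    cv_folds: int = 10
    cv_repeats: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pain_carry not in ("absorbing", "locf"):
            raise ValueError("pain_carry must be 'absorbing' or 'locf'")
        if self.landmark_coding not in ("s", "s_minus_1"):
            raise ValueError("landmark_coding must be 's' or 's_minus_1'")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")

    def replace(self, **changes) -> "PipelineConfig":
        from dataclasses import replace as _replace

        return _replace(self, **changes)


# ---------------------------------------------------------------------------
# Plain-text (YAML) round-tripping


def _config_to_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    gen = d["generator"]
    gen["true_coefficients"] = {
        k: float(v) for k, v in cfg.generator.true_coefficients.values.items()
    }
    gen["weekly_base_hazard"] = [float(x) for x in gen["weekly_base_hazard"]]
    gen["baseline_specs"] = {
        k: {kk: (None if not np.isfinite(vv) else float(vv)) for kk, vv in asdict(v).items()}
        for k, v in cfg.generator.baseline_specs.items()
    }
    return d


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(cfg), fh, sort_keys=True)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    gen = d.pop("generator")
    specs = {
        k: CovariateSpec(
            mean=v["mean"], sd=v["sd"],
            lower=-np.inf if v.get("lower") is None else v["lower"],
            upper=np.inf if v.get("upper") is None else v["upper"],
        )
        for k, v in gen.pop("baseline_specs").items()
    }
    coef = CoefficientSet(pd.Series(gen.pop("true_coefficients")))
    miss = MissingnessConfig(**gen.pop("missingness"))
    for key in ("education_probs", "reason_mixture", "weekly_base_hazard"):
        gen[key] = tuple(gen[key])
    generator = GeneratorConfig(
        baseline_specs=specs, true_coefficients=coef, missingness=miss, **gen
    )
    for key in ("eval_weeks",):
        d[key] = tuple(d[key])
    return PipelineConfig(generator=generator, **d)
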