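"""Synthetic recruit-cohort generator.

Generates cohorts with the statistical structure the landmarking analysis
assumes: truncated-normal baseline anthropometrics and fitness scores,
stationary AR(1) latent weekly self-report trajectories discretized to a
1-10 Likert scale, weekly Bernoulli pain reports, and dropout times drawn
from a discrete-time proportional-hazards process whose linear predictor
is exactly the supermodel's.  A truth record stores the latent series and
the hazard every recruit actually experienced, enabling oracle checks of
the estimation pipeline.

The generator is the study-conditions stand-in for a cohort that was never
deposited; its defaults are calibrated so that a 744-recruit cohort drops
out at 54.8% overall with 22% of dropouts inside the first four weeks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._rng import stream
from .config import GeneratorConfig, MissingnessConfig, default_weekly_base_hazard
from .design import (
    LIKERT_ITEMS,
    TV_COLS,
    baseline_design,
    landmark_code,
    tv_design,
)

__all__ = [
    "SimulatedCohort",
    "generate_baseline",
    "generate_trajectories",
    "simulate_dropout",
    "apply_missingness",
    "simulate_cohort",
    "required_cohorts",
    "events_per_predictor",
    "calibrate_base_hazard",
    "dropout_fractions",
]

REASONS = ["injury", "individual_request", "other"]
EXIT_ITEMS = ["exit_preparation", "exit_physical", "exit_mental", "exit_physician", "exit_injury"]

# Exit-survey item means conditional on the registered dropout reason; the
# statement matching the reason is elevated so the >=7 agreement rule is
# informative on synthetic data.
_EXIT_MEANS = {
    "injury": {"exit_preparation": 4.0, "exit_physical": 5.0, "exit_mental": 4.0,
               "exit_physician": 7.0, "exit_injury": 8.5},
    "individual_request": {"exit_preparation": 5.0, "exit_physical": 4.5, "exit_mental": 8.0,
                           "exit_physician": 2.0, "exit_injury": 2.0},
    "other": {"exit_preparation": 5.0, "exit_physical": 5.0, "exit_mental": 5.0,
              "exit_physician": 5.0, "exit_injury": 4.0},
}
_EXIT_SD = 1.5


@dataclass(frozen=True)
class SimulatedCohort:
    """One simulated cohort: three analysis tables plus the truth record.

    The truth tables are never read by the estimation pipeline; they exist
    so tests can replay the exact hazards the generator used.
    """

    baseline: pd.DataFrame
    weekly: pd.DataFrame
    outcomes: pd.DataFrame
    truth: pd.DataFrame
    config: GeneratorConfig

    def to_csv(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.baseline.to_csv(out / "baseline.csv", index=False)
        self.weekly.to_csv(out / "weekly_status.csv", index=False)
        self.outcomes.to_csv(out / "outcomes.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)


def _truncnorm(spec, rng: np.random.Generator, n: int) -> np.ndarray:
    """Sample a truncated normal whose REALIZED mean equals ``spec.mean``.

    The pre-truncation location is solved by root finding; with a lower
    bound close to the target mean relative to the SD this degenerates
    gracefully toward an exponential-like tail above the bound.
    """
    lo, hi, sd, target = spec.lower, spec.upper, spec.sd, spec.mean
    if not np.isfinite(lo) and not np.isfinite(hi):
        return rng.normal(target, sd, size=n)

    def realized_mean(mu: float) -> float:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return stats.truncnorm.mean(a, b, loc=mu, scale=sd)

    # realized_mean is increasing in mu; bracket widely.
    span = 50 * sd
    try:
        mu = optimize.brentq(lambda m: realized_mean(m) - target,
                             target - span, target + span, xtol=1e-10)
    except ValueError as err:
        raise ValueError(
            f"cannot calibrate truncation for target mean {target} within "
            f"bounds [{lo}, {hi}] (sd {sd}): {err}"
        ) from None
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)


def generate_baseline(config: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Baseline table: anthropometrics, fitness test and education per recruit.

    Covariates are independent truncated normals respecting the eligibility
    limits (minimum height/mass/fitness, age window); education is a
    three-level categorical with "unknown" as the reference.
    """
    rng = rng if rng is not None else stream(config.seed, "baseline")
    n = config.n_recruits
    data = {"recruit_id": np.arange(n, dtype=int)}
    for name, spec in config.baseline_specs.items():
        data[name] = _truncnorm(spec, rng, n) if n else np.empty(0)
    levels = np.array(["level_1", "level_2", "unknown"])
    data["education"] = (
        levels[rng.choice(3, size=n, p=list(config.education_probs))] if n else np.empty(0, dtype=object)
    )
    return pd.DataFrame(data)


def generate_trajectories(
    baseline: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Weekly observed status table and its latent truth.

    Per recruit and item, the latent series is a recruit-level intercept
    plus a stationary AR(1) deviation; the observed Likert value is the
    latent rounded and clamped to 1..10.  Pain reports are weekly Bernoulli
    draws with an NPRS severity of 1..10 when present.

    Returns ``(weekly, latent)`` in long format (one row per recruit-week).
    """
    phi = config.likert_ar_coef
    if not 0.0 < phi < 1.0:
        raise ValueError("likert_ar_coef must lie in (0, 1)")
    rng = rng if rng is not None else stream(config.seed, "trajectories")
    n = len(baseline)
    W = config.duration_weeks
    ids = baseline["recruit_id"].to_numpy()

    obs_cols: dict[str, np.ndarray] = {}
    lat_cols: dict[str, np.ndarray] = {}
    for item in LIKERT_ITEMS:
        mu = config.item_means[item]
        isd = config.item_intercept_sds[item]
        nsd = config.item_noise_sds[item]
        intercept = mu + isd * rng.standard_normal(n)
        dev = np.empty((n, W))
        if nsd > 0:
            stat_sd = nsd / math.sqrt(1.0 - phi * phi)
            dev[:, 0] = stat_sd * rng.standard_normal(n)
            eps = nsd * rng.standard_normal((n, W - 1))
            for w in range(1, W):
                dev[:, w] = phi * dev[:, w - 1] + eps[:, w - 1]
        else:
            dev[:] = 0.0
        latent = intercept[:, None] + dev
        lat_cols[item] = latent
        obs_cols[item] = np.clip(np.rint(latent), 1, 10).astype(int)

    pain = (rng.random((n, W)) < config.injury_weekly_prob).astype(int)
    nprs = np.where(pain == 1, rng.integers(1, 11, size=(n, W)), np.nan)

    rid = np.repeat(ids, W)
    week = np.tile(np.arange(1, W + 1), n)
    weekly = pd.DataFrame({"recruit_id": rid, "week": week})
    latent_df = pd.DataFrame({"recruit_id": rid, "week": week})
    for item in LIKERT_ITEMS:
        weekly[item] = obs_cols[item].ravel()
        latent_df[f"latent_{item}"] = lat_cols[item].ravel()
    weekly["pain_reported"] = pain.ravel()
    weekly["nprs"] = nprs.ravel()
    return weekly, latent_df


def _weekly_linear_predictors(
    baseline: pd.DataFrame, weekly: pd.DataFrame, config: GeneratorConfig
) -> np.ndarray:
    """True linear predictor per recruit-week, shape (n, duration_weeks).

    The hazard for week w (days 7(w-1)+1 .. 7w) uses the week-(w-1) status
    — exactly the value the landmark model sees at landmark s = w-1.  Week 1
    has no preceding survey, so only baseline covariates contribute.
    """
    coefs = config.true_coefficients
    n = len(baseline)
    W = config.duration_weeks
    xb = baseline_design(baseline).to_numpy() @ coefs.gamma.to_numpy()

    wk = weekly.sort_values(["recruit_id", "week"])
    item_mat = {
        c: wk.pivot(index="recruit_id", columns="week", values=c)
        .reindex(baseline["recruit_id"])  # align order
        .to_numpy()
        for c in LIKERT_ITEMS + ["pain_reported"]
    }
    ever_pain = np.maximum.accumulate(item_mat["pain_reported"], axis=1)

    lp = np.tile(xb[:, None], (1, W))
    b1 = coefs.beta1
    b2 = coefs.beta2
    for w in range(2, W + 1):
        s = w - 1
        code = landmark_code(s, config.landmark_coding)
        zvals = pd.DataFrame({c: item_mat[c][:, s - 1] for c in LIKERT_ITEMS})
        zvals["pain"] = ever_pain[:, s - 1]
        zc = tv_design(zvals, TV_COLS).to_numpy()
        lp[:, w - 1] += zc @ (b1.to_numpy() + code * b2.to_numpy())
    return lp


def simulate_dropout(
    baseline: pd.DataFrame,
    weekly: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    latent: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw dropout times, reasons and exit surveys; return (outcomes, truth).

    Week-w dropout probability is ``1 - exp(-h_w)`` with
    ``h_w = base_hazard[w] * exp(LP_i(w))``; the first success is the
    dropout week and the day is uniform within that week.  Completers are
    administratively censored at day ``7 * duration_weeks``.
    """
    rng = rng if rng is not None else stream(config.seed, "dropout")
    base = config.base_hazard_array()
    if (base < 0).any():
        raise ValueError("weekly base hazard must be non-negative")
    n = len(baseline)
    W = config.duration_weeks
    end_day = config.duration_days
    ids = baseline["recruit_id"].to_numpy()

    lp = _weekly_linear_predictors(baseline, weekly, config)
    hazard = base[None, :] * np.exp(lp)
    p_drop = 1.0 - np.exp(-hazard)

    u = rng.random((n, W))
    hit = u < p_drop
    first = np.where(hit.any(axis=1), hit.argmax(axis=1) + 1, 0)  # dropout week, 0 = completer

    # day within the dropout week: truncated-exponential under the constant
    # within-week hazard h/7 per day, so the generated process is exactly the
    # proportional-hazards process the partial likelihood estimates
    event = first > 0
    widx = np.clip(first - 1, 0, W - 1)
    h_at = hazard[np.arange(n), widx]
    u2 = rng.random(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = -np.log1p(-u2 * (1.0 - np.exp(-h_at))) * 7.0 / h_at
    day_in_week = np.clip(np.ceil(np.where(np.isfinite(frac), frac, 7 * u2)), 1, 7).astype(int)
    day = np.where(event, 7 * (first - 1) + day_in_week, end_day)

    # pain status at the time of dropout governs the injury-reason up-weighting
    wk = weekly.sort_values(["recruit_id", "week"])
    pain_mat = (
        wk.pivot(index="recruit_id", columns="week", values="pain_reported")
        .reindex(ids)
        .to_numpy()
    )
    ever_pain = np.maximum.accumulate(pain_mat, axis=1)
    week_idx = np.clip(np.where(event, first, W) - 1, 0, W - 1)
    pain_at_exit = ever_pain[np.arange(n), week_idx] > 0

    reason = np.full(n, "completed", dtype=object)
    drop_idx = np.flatnonzero(event)
    if drop_idx.size:
        q_injury, q_req, q_other = config.reason_mixture
        m = config.pain_reason_multiplier
        n_pain = int(pain_at_exit[drop_idx].sum())
        n_nopain = drop_idx.size - n_pain
        # solve the non-pain injury probability so the marginal injury share
        # stays at the configured mixture despite the up-weighting
        q0 = q_injury * drop_idx.size / max(n_nopain + m * n_pain, 1)
        probs_inj = np.clip(np.where(pain_at_exit[drop_idx], m * q0, q0), 0.0, 1.0)
        rest = 1.0 - probs_inj
        frac_req = q_req / (q_req + q_other)
        u2 = rng.random(drop_idx.size)
        r = np.where(
            u2 < probs_inj,
            "injury",
            np.where(u2 < probs_inj + rest * frac_req, "individual_request", "other"),
        )
        reason[drop_idx] = r

    outcomes = pd.DataFrame(
        {
            "recruit_id": ids,
            "event": event.astype(int),
            "day": day.astype(int),
            "reason": reason,
        }
    )

    # exit surveys for dropouts only
    for c in EXIT_ITEMS:
        outcomes[c] = np.nan
    outcomes["exit_survey_missing"] = 0
    if drop_idx.size:
        miss = rng.random(drop_idx.size) < config.exit_survey_missing_prob
        outcomes.loc[drop_idx, "exit_survey_missing"] = miss.astype(int)
        for c in EXIT_ITEMS:
            means = np.array([_EXIT_MEANS[r][c] for r in reason[drop_idx]])
            vals = np.clip(np.rint(means + _EXIT_SD * rng.standard_normal(drop_idx.size)), 1, 10)
            vals[miss] = np.nan
            outcomes.loc[drop_idx, c] = vals

    truth = pd.DataFrame(
        {
            "recruit_id": np.repeat(ids, W),
            "week": np.tile(np.arange(1, W + 1), n),
            "lp": lp.ravel(),
            "hazard": hazard.ravel(),
            "p_dropout": p_drop.ravel(),
        }
    )
    if latent is not None:
        truth = truth.merge(latent, on=["recruit_id", "week"], how="left")
    return outcomes, truth


def simulate_cohort(config: GeneratorConfig, degrade: bool = True) -> SimulatedCohort:
    """Full generator: baseline, trajectories, outcomes, truth, missingness.

    With ``degrade=False`` the complete (pre-missingness) cohort is returned.
    Fixing ``config.seed`` reproduces the cohort exactly.
    """
    baseline = generate_baseline(config)
    weekly, latent = generate_trajectories(baseline, config)
    outcomes, truth = simulate_dropout(baseline, weekly, config, latent=latent)
    # recruits keep weekly rows only while still in training
    week_of_day = np.ceil(outcomes.set_index("recruit_id")["day"] / 7).astype(int)
    last_week = weekly["recruit_id"].map(week_of_day)
    weekly = weekly[weekly["week"] <= last_week].reset_index(drop=True)
    cohort = SimulatedCohort(baseline, weekly, outcomes, truth, config)
    if degrade:
        cohort = apply_missingness(cohort, config.missingness)
    return cohort


def apply_missingness(
    cohort: SimulatedCohort,
    mcfg: MissingnessConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedCohort:
    """Degrade a complete cohort to the study's observed-data patterns.

    Erases baseline fields for a fraction of recruits; deletes the leading
    weeks of status for a left-truncated fraction; removes all status rows
    of (up to) a 1.4% fraction chosen among natural week-1 dropouts; punches
    sporadic gaps in the weekly items; and erases the mental-fitness item
    with probability increasing in (10 - latent value), with the intercept
    solved so the overall missing share matches the configured fraction
    (missing not at random).  Outcomes and the truth record are untouched.
    """
    mcfg = mcfg if mcfg is not None else cohort.config.missingness
    rng = rng if rng is not None else stream(cohort.config.seed, "missingness")
    baseline = cohort.baseline.copy()
    weekly = cohort.weekly.copy()
    n = len(baseline)
    if n == 0:
        return cohort

    cont_cols = list(cohort.config.baseline_specs.keys())

    # 1. baseline missingness: selected recruits lose >=1 continuous field
    sel = rng.random(n) < mcfg.p_missing_baseline
    for i in np.flatnonzero(sel):
        k = 1 + rng.binomial(len(cont_cols) - 1, 0.2)
        cols = rng.choice(cont_cols, size=k, replace=False)
        baseline.loc[baseline.index[i], cols] = np.nan

    drop_week = np.ceil(cohort.outcomes.set_index("recruit_id")["day"] / 7).astype(int)

    # 2. left truncation: delete the first k weeks of status
    trunc = rng.random(n) < mcfg.p_left_truncated
    kvec = rng.integers(1, mcfg.max_truncated_weeks + 1, size=n)
    cut = pd.Series(0, index=baseline["recruit_id"].to_numpy())
    for i in np.flatnonzero(trunc):
        rid = baseline["recruit_id"].iloc[i]
        # keep at least one observed week so the recruit stays analysable
        if drop_week.loc[rid] > kvec[i]:
            cut.loc[rid] = kvec[i]
    weekly = weekly[weekly["week"] > weekly["recruit_id"].map(cut)].reset_index(drop=True)

    # 3. week-1 dropouts without any observations: chosen among the natural
    # week-1 dropouts so the outcome table stays intact
    out = cohort.outcomes
    wk1 = out.loc[(out["event"] == 1) & (out["day"] <= 7), "recruit_id"].to_numpy()
    target = int(round(mcfg.p_week1_dropout_no_obs * n))
    if target and wk1.size:
        chosen = rng.choice(wk1, size=min(target, wk1.size), replace=False)
        weekly = weekly[~weekly["recruit_id"].isin(chosen)].reset_index(drop=True)

    # 4. survey-level nonresponse: whole weekly rows go missing (weeks >= 2,
    # so the left-truncation rate stays at its configured level); LOCF fills
    # these gaps downstream
    if mcfg.p_skip_week > 0 and len(weekly):
        skip = (rng.random(len(weekly)) < mcfg.p_skip_week) & (weekly["week"] > 1)
        weekly = weekly[~skip].reset_index(drop=True)

    # 5. MNAR mental fitness: P(missing) = sigmoid(alpha + strength*(10 - latent))
    if mcfg.p_mnar_mentalfit > 0 and len(weekly):
        lat = (
            cohort.truth.set_index(["recruit_id", "week"])["latent_mentalfit"]
            .reindex(pd.MultiIndex.from_frame(weekly[["recruit_id", "week"]]))
            .to_numpy()
        )
        gap10 = 10.0 - lat

        def mean_prob(alpha: float) -> float:
            return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + mcfg.mnar_strength * gap10)))))

        try:
            alpha = optimize.brentq(
                lambda a: mean_prob(a) - mcfg.p_mnar_mentalfit, -40.0, 40.0, xtol=1e-10
            )
        except ValueError:
            alpha = 0.0
        p = 1.0 / (1.0 + np.exp(-(alpha + mcfg.mnar_strength * gap10)))
        weekly.loc[rng.random(len(weekly)) < p, "mentalfit"] = np.nan

    return SimulatedCohort(baseline, weekly, cohort.outcomes, cohort.truth, cohort.config)


# ---------------------------------------------------------------------------
# Study-design arithmetic


def required_cohorts(
    target_events_per_predictor: float,
    recruits_per_cohort: float,
    dropout_rate: float,
    n_predictors: int,
) -> int:
    """Smallest number of cohorts achieving the target events-per-predictor.

    ``c * recruits_per_cohort * dropout_rate >= target * n_predictors``.
    """
    if min(target_events_per_predictor, recruits_per_cohort, n_predictors) <= 0:
        raise ValueError("all arguments must be positive")
    if dropout_rate <= 0:
        raise ValueError("dropout_rate must be positive: the target is unachievable")
    need = target_events_per_predictor * n_predictors
    per_cohort = recruits_per_cohort * dropout_rate
    return int(math.ceil(need / per_cohort - 1e-12))


def events_per_predictor(n_recruits: int = 744, dropout_rate: float = 0.5, n_predictors: int = 22) -> int:
    """Events-per-predictor of an available sample under a presumed dropout rate."""
    if n_recruits <= 0 or n_predictors <= 0 or not 0 < dropout_rate <= 1:
        raise ValueError("arguments must be positive (dropout_rate in (0, 1])")
    return int(round(n_recruits * dropout_rate / n_predictors))


# ---------------------------------------------------------------------------
# Calibration


def dropout_fractions(outcomes: pd.DataFrame, early_day: int = 28) -> tuple[float, float]:
    """(total dropout fraction, share of dropouts at/before ``early_day``)."""
    events = outcomes["event"] == 1
    total = float(events.mean()) if len(outcomes) else float("nan")
    n_ev = int(events.sum())
    early = float((outcomes.loc[events, "day"] <= early_day).mean()) if n_ev else float("nan")
    return total, early


def calibrate_base_hazard(
    config: GeneratorConfig | None = None,
    n: int = 40_000,
    seed: int = 977,
    target_total: float = 0.548,
    target_early_share: float = 0.22,
    early_weeks: int = 4,
) -> tuple[float, float]:
    """Solve the geometric base-hazard (scale, decay) for the dropout targets.

    Simulates one large set of covariate paths, then treats the expected
    dropout fractions as smooth deterministic functions of (scale, decay)
    and solves the two expected-dropout equations by nested root finding:
    given decay, the scale matching the total-dropout target is found by
    bisection (monotone); the outer root matches the early-dropout share.
    """
    cfg = (config or GeneratorConfig()).replace(n_recruits=n, seed=seed)
    baseline = generate_baseline(cfg)
    weekly, _ = generate_trajectories(baseline, cfg)
    lp = _weekly_linear_predictors(baseline, weekly, cfg)
    elp = np.exp(lp)
    W = cfg.duration_weeks
    wpow = np.arange(W, dtype=float)

    def fractions(scale: float, decay: float) -> tuple[float, float]:
        H = scale * decay**wpow * elp  # (n, W)
        cum = np.cumsum(H, axis=1)
        p_total = 1.0 - np.exp(-cum[:, -1])
        p_early = 1.0 - np.exp(-cum[:, early_weeks - 1])
        return float(p_total.mean()), float(p_early.mean() / p_total.mean())

    def scale_for(decay: float) -> float:
        return optimize.brentq(
            lambda a: fractions(a, decay)[0] - target_total, 1e-8, 5.0, xtol=1e-12
        )

    def early_resid(decay: float) -> float:
        return fractions(scale_for(decay), decay)[1] - target_early_share

    decay = optimize.brentq(early_resid, 0.7, 1.5, xtol=1e-10)
    scale = scale_for(decay)
    return float(scale), float(decay)
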