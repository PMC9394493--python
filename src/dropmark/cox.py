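"""Cox proportional-hazards estimation for the stacked landmark supermodel.

The partial likelihood is maximized by Newton-Raphson with step-halving
over event days pooled across the stacked rows.  Each row is at risk on
its (start, stop] interval; because the landmark windows partition the
timescale, risk sets form within each window automatically.  Breslow tie
handling is the default (Efron available), the cumulative baseline hazard
is the Breslow step-function estimator, and the variance is model-based
(inverse observed information) with a recruit-clustered sandwich option.

Design matrices are expected reference-centered (see :mod:`dropmark.design`),
so the estimated baseline hazard belongs to the reference subject and that
subject's linear predictor is exactly zero at every landmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import CoefficientSet, DESIGN_COLS, build_design, subject_design_row
from .landmarking import stack_landmarks
from .preprocess import CleanCohort

__all__ = [
    "CoxFit",
    "SupermodelFit",
    "fit_cox",
    "fit_supermodel",
    "pool_rubin",
    "linear_predictor",
    "conditional_dropout_probability",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass
class CoxFit:
    """A converged partial-likelihood fit."""

    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    n_rows: int
    n_events: int
    n_iter: int
    max_score: float
    ties: str
    variance_method: str
    baseline_hazard: pd.DataFrame  # columns: day, increment, cumhaz

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def summary(self) -> pd.DataFrame:
        """Coefficient table: log HR, HR, 95% CI and normal-theory p value."""
        se = self.se
        z = self.params / se
        return pd.DataFrame(
            {
                "coef": self.params,
                "hr": np.exp(self.params),
                "se": se,
                "hr_ci_lower": np.exp(self.params - 1.96 * se),
                "hr_ci_upper": np.exp(self.params + 1.96 * se),
                "p": 2 * stats.norm.sf(np.abs(z)),
            }
        )

    def cumhaz_at(self, t: float) -> float:
        """Right-continuous cumulative baseline hazard at day ``t``."""
        bh = self.baseline_hazard
        mask = bh["day"].to_numpy() <= t
        return float(bh.loc[mask, "increment"].sum())


def _check_design(X: np.ndarray, names: Sequence[str]) -> None:
    sd = X.std(axis=0)
    flat = [names[j] for j in np.flatnonzero(sd == 0)]
    if flat:
        raise ValueError(f"covariates with no variation (collinear with baseline): {flat}")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient (collinear columns)")


def _event_blocks(start: np.ndarray, stop: np.ndarray, event: np.ndarray):
    """Per distinct event day: indices at risk, indices of tied events."""
    times = np.unique(stop[event])
    blocks = []
    for t in times:
        risk = np.flatnonzero((start < t) & (stop >= t))
        ev = np.flatnonzero(event & (stop == t))
        blocks.append((float(t), risk, ev))
    return blocks


def _loglik_grad_hess(beta, X, blocks, ties):
    lp = X @ beta
    w = np.exp(lp)
    p = X.shape[1]
    ll = 0.0
    g = np.zeros(p)
    H = np.zeros((p, p))
    for _t, risk, ev in blocks:
        Xr = X[risk]
        wr = w[risk]
        d = len(ev)
        S0 = wr.sum()
        S1 = wr @ Xr
        S2 = (Xr * wr[:, None]).T @ Xr
        ll += lp[ev].sum()
        g += X[ev].sum(axis=0)
        if ties == "breslow" or d == 1:
            xbar = S1 / S0
            ll -= d * np.log(S0)
            g -= d * xbar
            H += d * (S2 / S0 - np.outer(xbar, xbar))
        elif ties == "efron":
            we = w[ev]
            Xe = X[ev]
            s0t = we.sum()
            s1t = we @ Xe
            s2t = (Xe * we[:, None]).T @ Xe
            for j in range(d):
                f = j / d
                den = S0 - f * s0t
                num1 = S1 - f * s1t
                num2 = S2 - f * s2t
                xbar = num1 / den
                ll -= np.log(den)
                g -= xbar
                H += num2 / den - np.outer(xbar, xbar)
        else:
            raise ValueError(f"unknown ties method {ties!r}")
    return ll, g, H


def _breslow_baseline(beta, X, blocks) -> pd.DataFrame:
    w = np.exp(X @ beta)
    days, incs = [], []
    for t, risk, ev in blocks:
        days.append(t)
        incs.append(len(ev) / w[risk].sum())
    inc = np.asarray(incs)
    return pd.DataFrame({"day": days, "increment": inc, "cumhaz": np.cumsum(inc)})


def _robust_cov(beta, X, blocks, hess_inv, cluster) -> np.ndarray:
    w = np.exp(X @ beta)
    n, p = X.shape
    U = np.zeros((n, p))
    for _t, risk, ev in blocks:
        wr = w[risk]
        S0 = wr.sum()
        xbar = (wr @ X[risk]) / S0
        d = len(ev)
        U[ev] += X[ev] - xbar
        U[risk] -= (d * wr / S0)[:, None] * (X[risk] - xbar)
    if cluster is not None:
        U = pd.DataFrame(U).groupby(np.asarray(cluster)).sum().to_numpy()
    B = U.T @ U
    return hess_inv @ B @ hess_inv


def fit_cox(
    X: pd.DataFrame,
    start,
    stop,
    event,
    *,
    cluster=None,
    ties: str = "breslow",
    variance: str = "model",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxFit:
    """Maximize the Cox partial likelihood on (start, stop] counting-process data.

    Parameters
    ----------
    X : DataFrame
        Design matrix (one column per covariate); should be centered for
        numerical stability and a meaningful baseline hazard.
    start, stop, event : array-like
        Risk interval (start, stop] and event indicator per row.
    cluster : array-like, optional
        Grouping labels (e.g. recruit ids) for the robust sandwich variance.
    ties : {"breslow", "efron"}
    variance : {"model", "robust"}

    Raises
    ------
    ValueError
        On zero events or collinear columns.
    ConvergenceError
        If the score max-norm does not fall below ``tol`` in ``max_iter``
        Newton iterations.
    """
    names = list(X.columns)
    Xm = np.asarray(X, dtype=float)
    start = np.asarray(start, dtype=float)
    stop = np.asarray(stop, dtype=float)
    event = np.asarray(event).astype(bool)
    if not event.any():
        raise ValueError("no events in the data; cannot fit")
    if np.any(stop <= start):
        raise ValueError("every row needs stop > start")
    _check_design(Xm, names)

    blocks = _event_blocks(start, stop, event)
    beta = np.zeros(Xm.shape[1])
    ll, g, H = _loglik_grad_hess(beta, Xm, blocks, ties)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(g)) <= tol:
            break
        try:
            delta = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(f"singular information matrix: {err}") from None
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            ll_new, g_new, H_new = _loglik_grad_hess(cand, Xm, blocks, ties)
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
        else:
            raise ConvergenceError(
                f"step-halving failed at iteration {n_iter} (loglik {ll:.6f})"
            )
        beta, ll, g, H = cand, ll_new, g_new, H_new
    max_score = float(np.max(np.abs(g)))
    if max_score > tol:
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations (max score {max_score:.3g}, "
            f"loglik {ll:.6f})"
        )

    hess_inv = np.linalg.inv(H)
    if variance == "model":
        cov = hess_inv
    elif variance == "robust":
        cov = _robust_cov(beta, Xm, blocks, hess_inv, cluster)
    else:
        raise ValueError(f"unknown variance method {variance!r}")

    return CoxFit(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        loglik=float(ll),
        n_rows=len(Xm),
        n_events=int(event.sum()),
        n_iter=n_iter,
        max_score=max_score,
        ties=ties,
        variance_method=variance,
        baseline_hazard=_breslow_baseline(beta, Xm, blocks),
    )


@dataclass
class SupermodelFit:
    """A fitted landmark supermodel plus the metadata needed to score subjects."""

    fit: CoxFit
    coding: str
    items: list[str]
    duration_weeks: int

    @property
    def coefficients(self) -> CoefficientSet:
        return CoefficientSet(self.fit.params)

    def summary(self) -> pd.DataFrame:
        return self.fit.summary()

    def linear_predictors(self, stacked: pd.DataFrame) -> pd.Series:
        """Reference-centered LP for each stacked recruit-landmark row."""
        design = build_design(stacked, coding=self.coding)
        return pd.Series(
            design.to_numpy() @ self.fit.params.reindex(design.columns).to_numpy(),
            index=stacked.index,
            name="lp",
        )


def fit_supermodel(
    clean: CleanCohort,
    coding: str = "s_minus_1",
    ties: str = "breslow",
    variance: str = "model",
    stacked: pd.DataFrame | None = None,
) -> SupermodelFit:
    """Stack a clean cohort and fit the 21-predictor landmark supermodel."""
    stacked = stacked if stacked is not None else stack_landmarks(clean)
    design = build_design(stacked, coding=coding)
    fit = fit_cox(
        design,
        stacked["start"],
        stacked["stop"],
        stacked["event"],
        cluster=stacked["recruit_id"],
        ties=ties,
        variance=variance,
    )
    return SupermodelFit(fit=fit, coding=coding, items=list(clean.items),
                         duration_weeks=clean.duration_weeks)


def pool_rubin(fits: Sequence[CoxFit] | Sequence[tuple[pd.Series, pd.DataFrame]]) -> pd.DataFrame:
    """Pool estimates across multiply imputed fits by Rubin's rules.

    Pooled estimate = mean of estimates; total variance = mean within-fit
    variance + (1 + 1/m) x between-fit variance; CIs from normal quantiles.
    With m = 1 the single fit is returned unchanged (between-variance 0).
    """
    if len(fits) == 0:
        raise ValueError("need at least one fit to pool")
    pairs = [
        (f.params, f.cov) if isinstance(f, CoxFit) else (f[0], f[1]) for f in fits
    ]
    index = pairs[0][0].index
    for est, _ in pairs[1:]:
        if not est.index.equals(index):
            raise ValueError("coefficient orderings differ across fits; cannot pool")
    m = len(pairs)
    est_mat = np.vstack([p[0].to_numpy() for p in pairs])
    within = np.vstack([np.diag(p[1].to_numpy()) for p in pairs]).mean(axis=0)
    pooled = est_mat.mean(axis=0)
    between = est_mat.var(axis=0, ddof=1) if m > 1 else np.zeros_like(pooled)
    total = within + (1 + 1 / m) * between
    se = np.sqrt(total)
    return pd.DataFrame(
        {
            "coef": pooled,
            "variance": total,
            "se": se,
            "hr": np.exp(pooled),
            "hr_ci_lower": np.exp(pooled - 1.96 * se),
            "hr_ci_upper": np.exp(pooled + 1.96 * se),
        },
        index=index,
    )


def linear_predictor(
    coefficients: CoefficientSet | pd.Series,
    subject: Mapping[str, float | str],
    s: int,
    coding: str = "s_minus_1",
) -> float:
    """Reference-centered log hazard of ``subject`` at landmark ``s``.

    ``subject`` carries raw covariate values (push-ups/sit-ups as counts,
    education as a category); the reference subject scores exactly 0.
    """
    coefs = coefficients.values if isinstance(coefficients, CoefficientSet) else coefficients
    row = subject_design_row(subject, s, coding=coding)
    return float(row.to_numpy() @ coefs.reindex(row.index).to_numpy())


def conditional_dropout_probability(
    model: SupermodelFit,
    subject: Mapping[str, float | str],
    s: int,
    horizon_weeks: int,
) -> float:
    """P(dropout by week s + horizon | in training at landmark s).

    Holds the subject's covariates at their landmark-s values:
    ``1 - exp(-(H0(7(s+h)) - H0(7s)) * exp(LP(s)))`` with ``H0`` the
    reference subject's Breslow cumulative hazard.
    """
    if horizon_weeks < 0:
        raise ValueError("horizon_weeks must be non-negative")
    end_day = 7 * (s + horizon_weeks)
    if end_day > 7 * model.duration_weeks:
        raise ValueError(
            f"horizon extends to day {end_day}, beyond training end "
            f"(day {7 * model.duration_weeks})"
        )
    lp = linear_predictor(model.fit.params, subject, s, coding=model.coding)
    dh = model.fit.cumhaz_at(end_day) - model.fit.cumhaz_at(7 * s)
    return float(1.0 - np.exp(-dh * np.exp(lp)))
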