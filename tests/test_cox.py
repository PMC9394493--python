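"""Cox solver tests: brute-force likelihood oracles, lifelines cross-checks,
Rubin pooling, linear predictors and conditional probabilities."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from dropmark.config import DEFAULT_TRUE_HAZARD_RATIOS
from dropmark.cox import (
    CoxFit,
    SupermodelFit,
    conditional_dropout_probability,
    fit_cox,
    fit_supermodel,
    linear_predictor,
    pool_rubin,
)
from dropmark.cox import _breslow_baseline, _event_blocks
from dropmark.design import CoefficientSet, REFERENCE_SUBJECT, build_design
from dropmark.landmarking import stack_landmarks


def brute_partial_loglik(beta, start, stop, event, X):
    """Independent double-loop Breslow partial log-likelihood (the oracle)."""
    beta = np.atleast_1d(beta)
    n = len(stop)
    ll = 0.0
    for t in sorted({stop[i] for i in range(n) if event[i]}):
        tied = [i for i in range(n) if event[i] and stop[i] == t]
        risk = [i for i in range(n) if start[i] < t <= stop[i]]
        s0 = sum(math.exp(float(X[i] @ beta)) for i in risk)
        for i in tied:
            ll += float(X[i] @ beta)
        ll -= len(tied) * math.log(s0)
    return ll


class TestPartialLikelihoodOracle:
    def test_three_row_toy_matches_brute_force(self):
        # one window (0, 7]; x = (0, 1, 1); event on an x=1 row at day 2,
        # then on the x=0 row at day 5; the remaining x=1 row is censored
        X = pd.DataFrame({"x": [0.0, 1.0, 1.0]})
        start = np.zeros(3)
        stop = np.array([5.0, 2.0, 7.0])
        event = np.array([1, 1, 0])
        fit = fit_cox(X, start, stop, event)
        res = optimize.minimize_scalar(
            lambda b: -brute_partial_loglik(np.array([b]), start, stop, event,
                                            X.to_numpy()),
            bounds=(-10, 10), method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.params["x"] == pytest.approx(res.x, abs=1e-6)
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-8)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_small_instances_match_brute_force(self, seed):
        """On <=6-row instances the Newton solver must agree with direct
        maximization of the written-out partial likelihood to 1e-4."""
        rng = np.random.default_rng(seed)
        for _ in range(40):
            n = rng.integers(3, 7)
            x = rng.integers(-1, 3, size=n).astype(float)
            window = rng.integers(0, 2, size=n)  # rows in one of two windows
            start = 7.0 * window
            stop = start + rng.integers(1, 8, size=n)
            event = rng.integers(0, 2, size=n)
            if event.sum() == 0 or np.std(x) == 0:
                continue
            X = pd.DataFrame({"x": x})
            try:
                fit = fit_cox(X, start, stop, event, max_iter=200)
            except Exception:
                continue  # monotone-likelihood instances have no finite MLE
            res = optimize.minimize_scalar(
                lambda b: -brute_partial_loglik(np.array([b]), start, stop, event,
                                                X.to_numpy()),
                bounds=(-15, 15), method="bounded", options={"xatol": 1e-10},
            )
            if abs(res.x) > 8:  # monotone likelihood: no finite maximizer
                continue
            assert fit.params["x"] == pytest.approx(res.x, abs=1e-4)

    def test_two_covariate_instance_matches_brute_force(self):
        rng = np.random.default_rng(42)
        n = 6
        X = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        start = np.zeros(n)
        stop = rng.integers(1, 8, size=n).astype(float)
        event = np.array([1, 0, 1, 1, 0, 1])
        fit = fit_cox(X, start, stop, event)
        res = optimize.minimize(
            lambda b: -brute_partial_loglik(b, start, stop, event, X.to_numpy()),
            x0=np.zeros(2), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        np.testing.assert_allclose(fit.params.to_numpy(), res.x, atol=1e-4)

    def test_constant_covariate_errors(self):
        X = pd.DataFrame({"x": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="no variation"):
            fit_cox(X, np.zeros(3), np.array([1.0, 2, 3]), np.array([1, 1, 0]))

    def test_zero_events_errors(self):
        X = pd.DataFrame({"x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="no events"):
            fit_cox(X, np.zeros(2), np.ones(2), np.zeros(2))


class TestLifelinesCrossCheck:
    """The solver vs an established implementation on the same data."""

    def test_supermodel_matches_cox_time_varying_fitter(self, clean_complete):
        lifelines = pytest.importorskip("lifelines")
        stacked = stack_landmarks(clean_complete)
        design = build_design(stacked)
        ours = fit_cox(design, stacked["start"], stacked["stop"], stacked["event"],
                       ties="efron")
        df = design.copy()
        df[["start", "stop", "event"]] = stacked[["start", "stop", "event"]]
        df["id"] = stacked["recruit_id"]
        ctv = lifelines.CoxTimeVaryingFitter()
        ctv.fit(df, id_col="id", start_col="start", stop_col="stop",
                event_col="event", show_progress=False)
        np.testing.assert_allclose(ours.params.to_numpy(), ctv.params_.to_numpy(),
                                   atol=1e-6)
        np.testing.assert_allclose(ours.se.to_numpy(),
                                   ctv.standard_errors_.to_numpy(), atol=1e-5)

    def test_baseline_model_matches_coxph_fitter(self, clean_complete):
        lifelines = pytest.importorskip("lifelines")
        from dropmark.design import baseline_design

        xb = baseline_design(clean_complete.baseline)
        out = clean_complete.outcomes.set_index("recruit_id").loc[
            clean_complete.baseline["recruit_id"]
        ]
        ours = fit_cox(xb, np.zeros(len(xb)), out["day"], out["event"], ties="efron")
        df = xb.copy()
        df["day"] = out["day"].to_numpy()
        df["event"] = out["event"].to_numpy()
        cph = lifelines.CoxPHFitter()
        cph.fit(df, duration_col="day", event_col="event")
        np.testing.assert_allclose(ours.params.to_numpy(), cph.params_.to_numpy(),
                                   atol=1e-4)


class TestBreslowBaseline:
    def test_reduces_to_nelson_aalen_at_zero_coefficients(self):
        X = np.zeros((5, 1))
        X[0, 0] = 1.0  # irrelevant at beta = 0
        start = np.zeros(5)
        stop = np.array([3.0, 5, 5, 5, 5])
        event = np.array([True, False, False, False, False])
        blocks = _event_blocks(start, stop, event)
        bh = _breslow_baseline(np.zeros(1), X, blocks)
        assert bh["increment"].iloc[0] == pytest.approx(1 / 5)

    def test_single_event_with_known_lps(self):
        # LPs (0, ln 2): exp-LP sum is 3, so the increment is 1/3
        X = np.array([[0.0], [1.0]])
        blocks = _event_blocks(np.zeros(2), np.array([2.0, 2.0]),
                               np.array([True, False]))
        bh = _breslow_baseline(np.array([math.log(2)]), X, blocks)
        assert bh["increment"].iloc[0] == pytest.approx(1 / 3)

    def test_cumulative_hazard_nondecreasing(self, clean_complete):
        model = fit_supermodel(clean_complete)
        cum = model.fit.baseline_hazard["cumhaz"].to_numpy()
        assert (np.diff(cum) >= 0).all()


class TestShiftInvariance:
    def test_covariate_shift_absorbed_by_baseline(self, clean_complete):
        """Adding a constant to a covariate (even a time-varying one whose
        interaction changes with the landmark) leaves all estimates unchanged:
        landmark windows partition time, so the shift is constant within every
        risk set."""
        stacked = stack_landmarks(clean_complete)
        d1 = build_design(stacked)
        fit1 = fit_cox(d1, stacked["start"], stacked["stop"], stacked["event"])
        shifted = stacked.copy()
        shifted["motivated"] = shifted["motivated"] + 3.0
        shifted["body_mass_kg"] = shifted["body_mass_kg"] + 10.0
        d2 = build_design(shifted)
        fit2 = fit_cox(d2, stacked["start"], stacked["stop"], stacked["event"])
        np.testing.assert_allclose(fit1.params.to_numpy(), fit2.params.to_numpy(),
                                   atol=1e-6)


class TestRubinPooling:
    def fake_fit(self, est, var):
        idx = ["a", "b"]
        return (pd.Series(est, index=idx), pd.DataFrame(np.diag(var), index=idx, columns=idx))

    def test_single_fit_is_identity(self):
        est, cov = self.fake_fit([1.0, -0.5], [0.04, 0.09])
        pooled = pool_rubin([(est, cov)])
        np.testing.assert_allclose(pooled["coef"], est)
        np.testing.assert_allclose(pooled["variance"], np.diag(cov))

    def test_hand_computed_two_fit_pool(self):
        # estimates 1.0 and 3.0 with equal within-variance v: pooled mean 2.0,
        # between-variance 2.0, total v + (1 + 1/2) * 2 = v + 3
        v = 0.25
        f1 = self.fake_fit([1.0, 1.0], [v, v])
        f2 = self.fake_fit([3.0, 3.0], [v, v])
        pooled = pool_rubin([f1, f2])
        assert pooled["coef"].iloc[0] == pytest.approx(2.0)
        assert pooled["variance"].iloc[0] == pytest.approx(v + 3.0)

    def test_identical_fits_have_zero_between_variance(self):
        f = self.fake_fit([0.7, -0.1], [0.01, 0.02])
        pooled = pool_rubin([f] * 5)
        np.testing.assert_allclose(pooled["variance"], [0.01, 0.02])

    def test_mismatched_orderings_error(self):
        f1 = self.fake_fit([1.0, 2.0], [0.1, 0.1])
        est2 = pd.Series([1.0, 2.0], index=["b", "a"])
        with pytest.raises(ValueError, match="orderings"):
            pool_rubin([f1, (est2, f1[1])])


class TestLinearPredictor:
    coefs = CoefficientSet.from_hazard_ratios(DEFAULT_TRUE_HAZARD_RATIOS)

    def test_reference_subject_scores_zero_everywhere(self):
        for s in (1, 2, 12, 23):
            assert linear_predictor(self.coefs, REFERENCE_SUBJECT, s) == pytest.approx(0.0)

    def test_motivation_effect_at_first_landmark(self):
        subject = dict(REFERENCE_SUBJECT, motivated=6.0)
        lp = linear_predictor(self.coefs, subject, 1)
        assert lp == pytest.approx(math.log(0.655), abs=1e-12)

    def test_motivation_effect_weakens_at_second_landmark(self):
        subject = dict(REFERENCE_SUBJECT, motivated=6.0)
        lp = linear_predictor(self.coefs, subject, 2)
        assert lp == pytest.approx(math.log(0.655) + math.log(1.018), abs=1e-12)

    def test_raw_landmark_coding_option(self):
        subject = dict(REFERENCE_SUBJECT, motivated=6.0)
        lp = linear_predictor(self.coefs, subject, 1, coding="s")
        assert lp == pytest.approx(math.log(0.655) + math.log(1.018), abs=1e-12)

    def test_missing_covariate_named_in_error(self):
        subject = dict(REFERENCE_SUBJECT)
        del subject["cooper_km"]
        with pytest.raises(ValueError, match="cooper_km"):
            linear_predictor(self.coefs, subject, 1)


def toy_supermodel(increments):
    """A SupermodelFit with a fabricated baseline hazard (for probability math)."""
    days, incs = zip(*increments)
    bh = pd.DataFrame({"day": days, "increment": incs, "cumhaz": np.cumsum(incs)})
    coefs = CoefficientSet.from_hazard_ratios(DEFAULT_TRUE_HAZARD_RATIOS)
    p = coefs.values
    fit = CoxFit(params=p, cov=pd.DataFrame(np.eye(21), index=p.index, columns=p.index),
                 loglik=0.0, n_rows=0, n_events=len(days), n_iter=0, max_score=0.0,
                 ties="breslow", variance_method="model", baseline_hazard=bh)
    return SupermodelFit(fit=fit, coding="s_minus_1", items=[], duration_weeks=24)


class TestConditionalProbability:
    def test_zero_horizon_is_zero(self):
        model = toy_supermodel([(10, 0.1)])
        assert conditional_dropout_probability(model, REFERENCE_SUBJECT, 1, 0) == 0.0

    def test_known_increment_closed_form(self):
        # H0 gains 0.1 in (7, 14]; reference subject (LP=0): 1 - exp(-0.1)
        model = toy_supermodel([(10, 0.1)])
        p = conditional_dropout_probability(model, REFERENCE_SUBJECT, 1, 1)
        assert p == pytest.approx(1 - math.exp(-0.1), abs=1e-12)

    def test_monotone_in_horizon_and_lp(self):
        model = toy_supermodel([(10, 0.05), (20, 0.05), (30, 0.05)])
        probs = [conditional_dropout_probability(model, REFERENCE_SUBJECT, 1, h)
                 for h in range(0, 4)]
        assert all(a <= b for a, b in zip(probs, probs[1:]))
        low = conditional_dropout_probability(
            model, dict(REFERENCE_SUBJECT, motivated=10.0), 1, 2)  # protective
        assert low < probs[2]

    def test_horizon_beyond_training_errors(self):
        model = toy_supermodel([(10, 0.1)])
        with pytest.raises(ValueError, match="beyond training end"):
            conditional_dropout_probability(model, REFERENCE_SUBJECT, 23, 2)


def test_parameter_recovery_single_cohort(clean_complete, complete_cohort):
    """With the generator's true coefficients as the target, a single clean
    cohort recovers the strong motivation effect within sampling error."""
    model = fit_supermodel(clean_complete)
    truth = complete_cohort.config.true_coefficients.values
    est, se = model.fit.params, model.fit.se
    assert abs(est["motivated"] - truth["motivated"]) < 3 * se["motivated"]
    assert abs(est["body_mass_kg"] - truth["body_mass_kg"]) < 3 * se["body_mass_kg"]
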