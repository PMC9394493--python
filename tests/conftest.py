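import numpy as np
import pandas as pd
import pytest

from dropmark.config import GeneratorConfig, MissingnessConfig
from dropmark.design import LIKERT_ITEMS, TV_COLS
from dropmark.preprocess import CleanCohort, preprocess
from dropmark.simulate import simulate_cohort


@pytest.fixture(scope="session")
def degraded_cohort():
    """A default-missingness cohort, small enough for fast unit tests."""
    return simulate_cohort(GeneratorConfig(n_recruits=250, seed=42))


@pytest.fixture(scope="session")
def clean_small(degraded_cohort):
    return preprocess(degraded_cohort)


@pytest.fixture(scope="session")
def complete_cohort():
    """A missingness-free cohort (estimator tests, truth replay)."""
    cfg = GeneratorConfig(n_recruits=300, seed=7, missingness=MissingnessConfig.none())
    return simulate_cohort(cfg, degrade=False)


@pytest.fixture(scope="session")
def clean_complete(complete_cohort):
    return preprocess(complete_cohort)


@pytest.fixture
def toy_clean_factory():
    """Factory for hand-built CleanCohort objects.

    ``recruits`` is a list of dicts with keys: day, event, entry_week
    (default 1) and optionally per-item constants (default: Likert 5,
    pain 0).  Baseline covariates are the reference subject's.
    """

    def build(recruits, duration_weeks=24):
        base_rows, weekly_rows, out_rows, entry_rows = [], [], [], []
        for i, r in enumerate(recruits):
            entry = r.get("entry_week", 1)
            base_rows.append({
                "recruit_id": i, "age": 23.0, "height_m": 1.80, "body_mass_kg": 80.0,
                "body_fat_pct": 14.0, "cooper_km": 2.8, "pushups": 55.0, "situps": 55.0,
                "education": "unknown",
            })
            out_rows.append({"recruit_id": i, "event": r["event"], "day": r["day"],
                             "reason": "individual_request" if r["event"] else "completed"})
            entry_rows.append({"recruit_id": i, "entry_week": entry})
            for w in range(1, duration_weeks + 1):
                row = {"recruit_id": i, "week": w}
                for item in TV_COLS:
                    default = 0.0 if item == "pain" else 5.0
                    row[item] = np.nan if w < entry else r.get(item, default)
                weekly_rows.append(row)
        items = [c for c in LIKERT_ITEMS if c != "mentalfit"] + ["pain"]
        return CleanCohort(
            baseline=pd.DataFrame(base_rows),
            imputation_log=pd.DataFrame(columns=["recruit_id", "column", "fill_value"]),
            weekly=pd.DataFrame(weekly_rows),
            items=items,
            entry=pd.DataFrame(entry_rows),
            exclusions=pd.DataFrame(columns=["recruit_id", "reason"]),
            outcomes=pd.DataFrame(out_rows),
            screen_report=pd.DataFrame(),
            duration_weeks=duration_weeks,
        )

    return build
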