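#!/usr/bin/env python
"""Repeated 10-fold cross-validation of the supermodel on the working cohort.

Folds split recruits (stratified by dropout status), never rows, so a
recruit's landmarks never leak between training and test.  Reports the
apparent and cross-validated AUC(t) with 2.5/97.5 percentile bands over
repeats; writes results/cohort/cv_auc.csv.
"""

from pathlib import Path

from dropmark.config import load_config
from dropmark.evaluate import cross_validate
from dropmark.pipeline import load_cohort
from dropmark.preprocess import preprocess

DATA = Path("results/cohort")
REPEATS = 20


def main() -> None:
    cfg = load_config(DATA / "config.yaml")
    clean = preprocess(load_cohort(DATA), max_missing_frac=cfg.max_missing_frac,
                       min_variance=cfg.min_variance, pain_carry=cfg.pain_carry)
    cv = cross_validate(clean, k=cfg.cv_folds, repeats=REPEATS, seed=cfg.seed,
                        eval_days=[7 * w for w in cfg.eval_weeks],
                        window_days=cfg.roc_window_days, coding=cfg.landmark_coding)
    table = cv.summary()
    table.rename_axis("day").round(6).to_csv(DATA / "cv_auc.csv")
    print(f"{cfg.cv_folds}-fold cross-validation, {REPEATS} repeats")
    print(table.round(3).to_string())
    optimism = (table["apparent"] - table["cv_mean"]).mean()
    print(f"mean optimism (apparent - cross-validated AUC): {optimism:+.3f}")


if __name__ == "__main__":
    main()
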