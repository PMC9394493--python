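# dropmark

Dynamic prediction of dropout from a 24-week military recruit training
programme, for biostatisticians and sports-medicine researchers working
with longitudinal monitoring data. The package implements a **Cox
proportional-hazards landmarking supermodel**: the course is divided into
S = 23 nonoverlapping weekly landmarks, a risk-set dataset is built at each
landmark from the recruits still in training, and the stacked datasets are
fitted jointly with the hazard

    h(t | Z(s), s) = h0(t) · exp( Z(s)·(β1 + β2·code(s)) + X·γ )

with `code(s) = s − 1` by default, so that β1 is the effect at the first
landmark and β2 its weekly drift. A recruit's risk is re-estimated every week from their fixed entry
characteristics X (anthropometrics, fitness test, education) and their
current self-reported health status Z(s) (five 10-point Likert items plus a
musculoskeletal-pain indicator). Discrimination is assessed with the
incident/dynamic time-dependent AUC(t) and Youden-optimal thresholds, and
validated by repeated 10-fold cross-validation with folds that split
recruits, never rows. Because the original training records are not
publicly deposited, a calibrated synthetic cohort generator reproduces the
study conditions (baseline distributions, 54.8% dropout with 22% in the
first four weeks, reason mixture, missingness patterns) so the whole
pipeline is testable offline; see `docs/methods.md` for the model, the
generator and their assumptions.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
cohort (each writes its tables under `results/cohort/`):

```bash
python analysis/02_simulate_cohort.py
python analysis/03_fit_supermodel.py
python analysis/04_evaluate_discrimination.py
python analysis/05_cross_validate.py
```

The simulation step prints

```
simulated 744 recruits -> results/cohort
dropout: 56.3% total, 23.4% of dropouts in weeks 1-4
registered reasons: {'individual_request': 251, 'injury': 133, 'other': 35}
```

— one cohort of 744 recruits whose dropout behaviour matches the
calibrated targets up to sampling noise. Fitting then reports 363 window
events over 11,926 stacked recruit-landmark rows (17.3 events per
predictor) and the 21-coefficient table; for instance the motivation item
comes out at HR 0.721 (95% CI 0.639–0.813) with a per-landmark interaction
of 1.015 — a strong early protective effect that weakens over the course,
recovering the generator's true values 0.655 and 1.018 within sampling
error. Evaluation prints the time-dependent discrimination:

```
week  1: AUC 0.820  optimal threshold -0.77  sensitivity 0.88  specificity 0.67
week  4: AUC 0.717  optimal threshold -0.84  sensitivity 0.80  specificity 0.64
week 12: AUC 0.667  optimal threshold -0.65  sensitivity 0.61  specificity 0.69
```

A recruit whose current linear predictor exceeds the week's threshold
(e.g. −0.77 at week 1, on the log-hazard-ratio scale centered at the
reference subject) would be flagged for elevated dropout risk.
Cross-validation (10 folds, 20 repeats) shows a small optimism: apparent
AUC 0.820/0.717/0.667 against cross-validated 0.804/0.695/0.647 at weeks
1/4/12.

The same pipeline is scriptable end-to-end with a manifest:

```bash
dropmark run --seed 1 --out results/run1      # or: python -m dropmark.cli
dropmark crossval --data results/run1 --k 10 --repeats 20 --seed 1
```

## Layout

```
src/dropmark/        library: simulate, preprocess, landmarking, cox,
                     evaluate, pipeline, cli, config, design
analysis/            numbered drivers for the study steps
tests/               unit, property and acceptance suites
scripts/acceptance.py
docs/methods.md      model, generator, assumptions, limitations
```
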