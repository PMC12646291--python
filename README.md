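# piloscore

Additive preoperative severity scoring for pilonidal disease, with the
full validation pipeline around it: cohort description, two-group
statistical comparison with expected-count-driven test selection, and
ROC-based cutoff analysis — all exercisable on synthetic cohorts.

## What's inside

| module | contents |
|---|---|
| `piloscore.records` | `PatientRecord`, field-level validation |
| `piloscore.score` | nine-factor weight table, `compute_score`, `classify_risk`, `score_bounds` |
| `piloscore.stats` | descriptives, uncorrected Pearson χ², Fisher exact, fixed-margin Monte-Carlo χ², pooled-variance t, Mann-Whitney U, Shapiro-Wilk gating, `compare_groups` report |
| `piloscore.roc` | ROC staircase, trapezoid/concordance AUC with Hanley-McNeil or DeLong CI, Youden cutoff, confusion-matrix metrics |
| `piloscore.cohort` | deterministic reconstruction fixture (156 patients matching the published group margins), outcome-conditional and prospective (logistic-link) simulators |
| `piloscore.cli` / `piloscore.io` | CLI, cohort CSV dialect, YAML configs |

The default weight table (9 factors, totals 10–27, high risk at ≥ 21):
BMI ≥ 30 → 2 else 1; male → 2 else 1; hairy back → 2 else 1;
diabetes → 3 else 1; prior recurrence → 3 else 1; midline pits
< 5 → 2, 5–10 → 4, > 10 → 6; lateral pits → 3 else 1; distance to anus
≤ 5 cm → 3 else 1; prior abscess → 3 else 1.

## CLI

```sh
# deterministic reconstruction fixture (157 lines: header + 156 records)
piloscore fixture --out fixture.csv

# score a cohort (appends per-factor points, total, risk class)
piloscore score --input fixture.csv --out scored.csv

# score one patient from flags
piloscore score --sex male --bmi 34 --hairy-back --diabetes \
    --prior-recurrence --n-midline-pits 12 --lateral-pits \
    --distance-to-anus-cm 3 --prior-abscess

# full validation bundle: comparison table + ROC + cutoff metrics
piloscore validate --input fixture.csv --out report/ --seed 1 --plot

# ROC metrics only
piloscore roc --input fixture.csv --out roc.json --points points.tsv

# synthetic cohorts (reproducible under --seed)
piloscore simulate --mode conditional --n 500 --seed 7 --out sim.csv
piloscore simulate --mode prospective --n 500 --seed 7 --out sim2.csv
```

Exit codes: 0 success, 2 validation/config error, 3 I/O error,
4 degenerate statistics (e.g. single-class outcome).

Defaults reproduce the reference analysis settings with no flags:
cutoff 21, α = 0.05, uncorrected χ², two-sided p-values.

## Notes

- The fixture is one admissible completion of the published margins: all
  categorical cell counts and the 12/2 high-score split are exact; the
  continuous fields are quantile-spaced to the published group moments
  (means within 0.5).
- ROC performance is apparent (resubstitution); no cross-validation.
- No multiple-testing correction is applied anywhere, matching the
  reference analysis.
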