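# hospdea

Data Envelopment Analysis (DEA) toolkit for small hospital panels, built
around a 2015–2024 panel of three Polish county hospitals (BIA, LOM, SUW).
It implements the full workflow of a two-model hospital efficiency study:

- **Radial input-oriented DEA** under constant (CCR), variable (BCC) and
  non-increasing returns to scale, with two-phase slack maximisation,
  scale efficiency `SE = TE_CCR / PTE_BCC`, and returns-to-scale
  classification via the CCR reference-weight sum (cross-checked against the
  CRS/NIRS/VRS score ordering).
- **Smoothed homogeneous bootstrap** (reflection method) for bias-corrected
  efficiency scores and confidence intervals, plus a naive resampling
  bootstrap for comparison.
- **Second-stage truncated regression**: maximum likelihood for a left-
  truncated normal regression of inefficiency on environmental covariates
  (occupancy, length of stay, contract-physician share, period dummies),
  with analytic gradient and observed-information standard errors.
- **Study pipeline**: per-year or pooled frontiers for an *operational*
  domain (staffing and beds producing hospitalisations and surgical
  procedures) and a *financial* domain (costs, staff and beds producing
  revenue and activity), period means (pre-pandemic 2015–19, pandemic
  2020–21, post-pandemic 2022–24), inefficiency decomposition into pure and
  scale parts, returns-to-scale tallies, and a DMU-adequacy rule
  `n >= max(m*s, 3*(m+s))`.
- **Synthetic generator**: Cobb–Douglas technologies with known true
  efficiency, a crisis shock that suppresses outputs in chosen years, and a
  truncated-regression data generator — used throughout the tests to
  validate the estimators against ground truth.

All envelopment programs are solved with `scipy.optimize.linprog` (HiGHS),
batched into block-diagonal LPs so that a full bootstrap costs a handful of
solver calls.

## Quick example

```python
from hospdea.panel import load_fixture_panel
from hospdea.pipeline import StudyConfig, run_study
from hospdea.bootstrap import BootstrapConfig

panel = load_fixture_panel()          # packaged 3-hospital, 10-year panel
config = StudyConfig(
    frontier_scope="pooled",          # one frontier across all 30 DMUs
    fallback="drop_surgical",         # the published panel lacks surgery counts
    bootstrap=BootstrapConfig(B=500, seed=1),
    seed=1,
)
report = run_study(panel, config)
print(report.period_means_deterministic.head())
print(report.decomposition)
```

Output (abridged):

```
      domain hospital  measure         period      mean
0  financial      BIA   te_ccr   pre_pandemic  0.870588
1  financial      BIA   te_ccr       pandemic  0.790169
2  financial      BIA   te_ccr  post_pandemic  0.914376
3  financial      BIA   te_ccr        overall  0.867641
4  financial      BIA  pte_bcc   pre_pandemic  0.871307
```

and the decomposition table reports, per domain/hospital, the overall
radial inefficiency together with its pure-technical and scale components
(they satisfy `overall = pure + scale` exactly).

## Repository layout

- `src/hospdea/` — the library: `panel` (I/O, validation, derived
  indicators), `dea` (LP core), `bootstrap`, `second_stage`, `pipeline`,
  `synthetic`, plus the packaged panel CSV under `data/`.
- `analysis/` — numbered drivers that reproduce the study end to end and
  write tables under `results/`:
  1. `01_fixture_overview.py` — throughput and 2024-vs-2015 percent changes.
  2. `02_fixture_study.py` — pooled and per-year efficiency studies of the
     packaged panel (with adequacy warnings for the per-year design).
  3. `03_synthetic_study.py` — ground-truth panel with a pandemic-style
     shock; shows the dip-and-rebound in measured efficiency.
  4. `04_bootstrap_calibration.py` — confidence-interval coverage against
     known true scores.
  5. `05_second_stage_recovery.py` — truncated-MLE parameter recovery.
- `scripts/acceptance.py` — emits the headline computed quantities as JSON:
  `python scripts/acceptance.py --seed 1 --out results/acceptance.json`.
- `tests/` — unit, property and oracle tests plus `test_acceptance.py`;
  `docs/methods.md` documents the models and numerical choices.

## Testing

```
python -m pytest -q tests/
```

The non-acceptance suite runs in about a minute. `tests/test_acceptance.py`
additionally runs Monte-Carlo calibration studies (bootstrap coverage over
800 synthetic datasets, regression recovery over 100 fits) and takes about
17 minutes; deselect it with `-k "not acceptance"` for quick iteration.
One acceptance test is expected to fail: four percent-change cells printed
in the published summary table cannot be reproduced from the published
yearly values under any consistent rounding rule (see
`docs/methods.md#known-data-discrepancies`); the test intentionally asserts
every printed cell rather than excluding the inconsistent ones.

## Reproduction

```
python analysis/01_fixture_overview.py
python analysis/02_fixture_study.py --seed 1
python analysis/03_synthetic_study.py --seed 7
python analysis/04_bootstrap_calibration.py --datasets 100
python analysis/05_second_stage_recovery.py --replicates 100
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All randomness flows through a single master seed per run via
`hospdea.bootstrap.derive_seed`, so every table above is bit-reproducible.
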