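# Methods

This document records the statistical models and the numerical choices made
in `hospdea`, in enough detail to re-derive every number the package
produces.

## 1. Panel and domains

A panel row is one hospital-year with staffing (employed and contract
physicians and nurses, other medical staff), capacity (beds), activity
(hospitalisations, optional surgical procedures, average length of stay,
bed occupancy) and finances (operating costs, net revenue). Derived
indicators:

- headcounts: `physicians = physicians_employed + physicians_contract`,
  likewise nurses;
- throughput: `hospitalisations / beds` per year;
- percent change between two years: `100 * (last - first) / first`.

Reported values are rounded half-away-from-zero (`round_half_away`), the
convention used in the published tables the fixture reproduces.

Two DEA domains are predefined:

- **operational**: inputs (physicians, nurses, other medical staff, beds),
  outputs (hospitalisations, surgical procedures);
- **financial**: inputs (operating costs, total staff, beds), outputs
  (net revenue, hospitalisations, surgical procedures).

The packaged panel does not include surgical procedures, so the pipeline
offers explicit fallbacks: `drop_surgical` switches to documented
reduced-output variants of both domains, `synthetic_surgical` imputes a
flagged synthetic series; the default `none` raises `MissingOutputError`.

## 2. DEA core

For DMU `o` with inputs `x_o` and outputs `y_o`, the input-oriented radial
envelopment program is

```
min  theta
s.t. X lambda <= theta * x_o
     Y lambda >= y_o
     lambda >= 0
     (VRS: sum lambda = 1;  NIRS: sum lambda <= 1;  CRS: free)
```

solved with `scipy.optimize.linprog` (HiGHS). A second phase maximises the
slack sum at fixed `theta` to obtain a Pareto-efficient reference point.
Independent programs (all DMUs of a frontier, or all DMUs of many bootstrap
replicates) are assembled into one block-diagonal sparse LP and handed to
HiGHS in a single call; tests verify the batched scores equal the
one-at-a-time scores to machine precision.

Scale efficiency is `SE = TE_CRS / TE_VRS`. Returns-to-scale labels come
from the CRS reference-weight sum `sum(lambda)` over optimal solutions
(interval rule: `< 1` increasing, `= 1` constant, `> 1` decreasing, at
tolerance 1e-6), cross-checked against the equivalent CRS/NIRS/VRS score
ordering rule.

Numerical tolerances: efficiency classification 1e-6, score comparisons
1e-7. An infeasible evaluation (possible under VRS when a unit lies outside
the convex hull in output space) is reported as `nan` with a non-optimal
status rather than raised.

## 3. Smoothed homogeneous bootstrap

Given estimated scores `theta_hat_1..n` for one frontier:

1. Reflect the sample around 1: `{theta_hat} ∪ {2 - theta_hat}`.
2. Bandwidth `h = 0.9 * min(sd, IQR/1.349) * (2n)^(-1/5)` computed on the
   reflected sample.
3. Draw `theta*` by resampling the reflected sample, adding `h * N(0,1)`,
   applying the variance correction
   `theta** = mean + (theta* - mean) / sqrt(1 + h^2 / sigma_hat^2)`
   (with `sigma_hat^2` the reflected-sample variance and `mean` the mean of
   the draw), and reflecting back into `(0, 1]` via `2 - value` for values
   above 1.
4. Rescale the original inputs by `theta_hat_i / theta**_i`, re-solve the
   DEA program for every DMU against the perturbed reference set, and
   record the replicate scores.
5. Bias `= mean(theta*_b) - theta_hat`; bias-corrected score
   `theta_tilde = 2*theta_hat - mean(theta*_b)` (reported only when the
   usual `bias^2 > var/3` rule of thumb does not reject it — otherwise the
   original estimate is kept and the interval still reflects the replicate
   spread).

Two interval styles are provided:

- `percentile` (default): the `alpha/2` and `1-alpha/2` quantiles of the
  replicate distribution, matching common applied reporting;
- `bias-corrected-basic`: `(2*theta_hat - q_{1-alpha/2},
  2*theta_hat - q_{alpha/2})`, the reflected/basic interval whose coverage
  of the *true* score can be checked on synthetic data. Intervals are
  clamped to `(0, 1]` and the clamping is flagged.

Replicates that fail to solve are dropped; if more than
`max_dropped_frac` (default 1%) are lost the run raises. A degenerate
sample (all scores numerically identical) short-circuits to the
point-mass answer rather than dividing by a zero bandwidth.

### Coverage experiment design

Calibration uses a single-input single-output CRS technology with known
true scores. In that setting the bootstrap has a useful closed form: every
replicate score is `theta_hat_i / max_j(star_j)`, so all DMUs in one
dataset share a single coverage event determined by `M = max theta_true`.
Each dataset therefore contributes one Bernoulli trial, and the experiment
must be sized in *datasets*, not DMUs. The acceptance test uses 800
independent datasets (Monte-Carlo s.e. about 1 percentage point); the
long-run coverage of the 95% basic interval in this design, measured over
1800 independent datasets, is about 0.92 — the well-known mild
undercoverage of the homogeneous bootstrap at small n.

## 4. Second-stage truncated regression

Inefficiency `u_i = max(0, 1 - score_i)` is regressed on covariates with a
left-truncated normal likelihood: `u_i = x_i' beta + eps_i`, `eps_i` normal
with the observed `u_i > point` (default 0). Log-likelihood per observation:

```
log phi((u - x'beta)/sigma) - log(sigma) - log(1 - Phi((point - x'beta)/sigma))
```

Maximisation is BFGS on `(beta, log sigma)` with the analytic gradient; the
`log sigma` parameterisation keeps the scale positive and makes the
numerical Hessian (`statsmodels approx_hess3`) well behaved. Standard
errors come from the observed information, mapped back to `sigma` by the
delta method. Convergence is declared when BFGS succeeds or when the
final gradient is negligible at the objective's scale
(`max|grad| <= 1e-3 * max(1, |loglik|)`) — BFGS routinely stops with
"precision loss" at points that are first-order optimal to far better than
statistical accuracy.

Exact-zero responses (efficient units) are incompatible with a
left-truncated-at-zero model; they are either nudged by 1e-9 (default) or
dropped, and the count is reported. Zero-variance covariates are dropped
with a note; a constant response raises `DegenerateSampleError`; rank
deficiency raises `CollinearityError`. Marginal effects are reported as
`coefficient * delta` for a `delta`-unit covariate change.

## 5. Pipeline

`run_study` evaluates both domains under per-year frontiers (`n = 3` per
year — the design of the original small-panel study, emitted with
DMU-adequacy warnings) or one pooled frontier over all 30 hospital-years.
The adequacy rule is `n >= max(m*s, 3*(m+s))`: 18 for the 4-input
2-output operational model, 15 for the 3-input 2-output financial model.

Period means aggregate yearly scores over pre-pandemic (2015–19), pandemic
(2020–21) and post-pandemic (2022–24) windows; the overall mean is the
length-weighted combination of the period means. Inefficiency decomposes as

```
(1 - TE_CRS) = (1 - PTE_VRS) + (PTE_VRS - TE_CRS)
   overall        pure              scale
```

an exact identity also enforced on the reported percentages (one decimal,
half-away-from-zero). Returns-to-scale tallies count per-period labels and
must conserve the number of hospital-years.

All seeds derive from a single master via `SeedSequence`-based
`derive_seed(master, *keys)`, so every report is bit-reproducible.

## 6. Synthetic generator

Efficient input bundles are drawn uniformly in per-input ranges; the latent
frontier output is Cobb–Douglas `A * prod(x_k^alpha_k)` split across
outputs by fixed weights; true efficiency `theta_true = exp(-|N(0, 0.15)|)`
scales the *inputs* outward (input orientation), so measured radial scores
are bounded below by `theta_true` whenever the frontier is weakly concave
— guaranteed for `sum(alpha) <= 1` (CRS or decreasing returns). For
increasing returns the inner-frontier guarantee does not hold and the
generator is not used to validate score bounds. A `Shock` multiplies the
outputs of chosen years (default 2020–21) by `delta` (default 0.7),
reproducing a pandemic-style activity drop with unchanged capacity.

## Known data discrepancies

Four percent-change cells printed in the published indicator table cannot
be reproduced from the published yearly values under any single rounding
convention (they appear to have been computed from unrounded source data or
to contain typos): the LOM employed-physician change (printed 2, computed
0), the BIA length-of-stay change (27 vs 26), the LOM length-of-stay
change (-5 vs -6) and the BIA occupancy change (32 vs 31). The
corresponding acceptance test checks every printed cell and is therefore
expected to fail on exactly these four; it was deliberately not weakened.
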