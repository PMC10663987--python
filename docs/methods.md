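# Methods

`dosecurve` fits per-gene dose-response models to log2 expression measured
across a compound dilution series with vehicle (DMSO) controls, tests every
nonzero concentration against the vehicle baseline, and — for spline-fitted
genes — reports the direction, efficacy and potency of the compound-gene
interaction with closed-form standard errors. This note records the model,
the numerical choices, and what the synthetic benchmarks do and do not show.

## Dose axis and the pseudo-concentration

Concentration enters every model as `x = log10(dose)`. Vehicle wells have
dose 0, which the log axis cannot hold; they are placed at a
pseudo-concentration one dilution step below the smallest tested dose,

    cp = log10(d_min) - log10(F),

where `F` is the dilution factor of the series. `F` is inferred from the
dose ladder when the successive ratios agree to within 15% (a geometric
series), can be supplied explicitly, and falls back to 10 otherwise. `cp`
is carried through all outputs: linear-scale potencies are reported as
`10**(log10_xc50 - cp)` in the experiment's dose unit, so the convention is
always invertible. Doses are rounded to 4 significant figures before
grouping, because instance metadata stores them with float jitter.

## Model families and the gate

With `C` distinct nonzero concentrations:

* `C > 4` — penalized-spline GAM: `y_i = f(x_i) + eps_i`, with
  `f(x) = b(x) beta` a thin-plate regression spline. With `K > 1` time
  points each time level gets its own coefficient vector over one shared
  basis: `y_i = sum_k f_k(x_i) 1[t_i = k] + eps_i`.
* `C <= 4` — robust cell-means ANOVA: `y_mkj = mu_mk + eps_mkj` with
  concentration (and time) categorical, fitted by Huber M-estimation.
* An OLS version of the ANOVA model is kept purely as the non-robust
  baseline for robustness comparisons; it is never selected by the gate.

### Spline construction

The basis is an eigen-truncated thin-plate regression spline on the unique
design points: radial kernel `|x - x'|^3`, leading eigenvectors of the
kernel matrix retained, the thin-plate side constraint absorbed, for a
total dimension of `J = 4` per time level *including* the two-dimensional
`{1, x}` penalty null space. A straight line is therefore reproduced
exactly at zero penalty, and the maximum effective degrees of freedom per
time level is 4. When fewer than `J` distinct design points exist the
dimension degrades to the number of points; fewer than 3 distinct points is
an error (such designs belong to the ANOVA path anyway).

The smoothing parameter is chosen by GCV,
`n * RSS(lambda) / (n - gamma * tr(A))^2`, minimized over
`log10(lambda) in [-8, 8]` by a 33-point grid scan followed by bounded
Brent refinement around the grid optimum. The df-charge `gamma` defaults
to 1 (the toolchain convention); `gamma ~ 1.4` is exposed for users who
want a stronger guard against GCV undersmoothing. Fitting is done in an
orthogonal reparametrization (Cholesky of X'X, eigendecomposition of the
transformed penalty), which makes each GCV evaluation O(p) and the whole
fit a fraction of a millisecond — this is what keeps the bootstrap
benchmarks cheap.

The coefficient covariance defaults to the Bayesian posterior form
`sigma^2 (X'X + lambda S)^{-1}` with `sigma^2 = RSS / (n - edf)`; these
intervals are the standard choice for penalized splines because they
partially account for smoothing bias. The frequentist sandwich form is
available via `coef_cov="sandwich"`. Cross-checks against the reference
GAM toolchain (R mgcv, `s(x, k=4)`, GCV) on identical data agree on
contrast estimates to ~1e-9 and on standard errors to well under 2%
(median), with residual differences traceable to the different smoothing
optimizers; this comparison is part of the test-suite.

### Robust ANOVA

Huber psi with tuning constant 1.345, scale by rescaled MAD, IRLS to
relative coefficient tolerance 1e-8 or 50 iterations (statsmodels RLM
provides the solver and the standard M-estimation asymptotic covariance).
With no residual beyond the Huber threshold the estimates equal OLS. If
all replicates are identical (zero MAD) the fit degenerates to exact cell
means with zero covariance and a flag; downstream tests then return NaN
p-values rather than false certainty. Residual df is `n - p` with `p` the
number of cells.

## Differential expression

The contrast at tested concentration `x*` is `(b(x*) - b(cp)) beta` for
splines, or the difference of cell means, with SE propagated through the
coefficient covariance. The t-statistic is referred to a t distribution
with the model's residual degrees of freedom (`n - edf`, non-integer for
splines). P-values are Benjamini-Hochberg adjusted **within each
(experiment, dose, time) stratum** — the family is recorded in the output
metadata so users can re-adjust across a different family. Significance is
called at adjusted p < 0.05.

Calibration caveat: with GCV-adaptive smoothing the null rejection rate is
slightly above nominal (~0.06 at alpha = 0.05 in the null benchmark), and
the robust-ANOVA path shows the usual small-sample anticonservatism of
M-estimation standard errors (~0.063 at n = 15). Both effects are
reproduced by the reference toolchains on identical data, i.e. they are
properties of the method, not of this implementation.

## Potency and efficacy

Defined only for spline fits (a cell-means model has no curve). On the
fitted curve over `[cp, x_max]`:

* `y0 = f(cp)`; extrema located on a 512-point grid with interior
  candidates refined to a stationary point (`|f'|` bracketing + Brent).
  A rank-4 curve cannot oscillate faster than this grid resolves.
* Direction: activator iff the rise `ymax - y0` exceeds the drop
  `y0 - ymin`; exact ties are classified inhibitor and flagged.
* Efficacy `log2 max effect = y_ext - y0`, SE from the linear contrast
  `c = b(x_ext) - b(cp)`.
* Potency `x50`: the smallest `x` in `(cp, x_ext]` with
  `f(x) = (y0 + y_ext)/2`, found by sign scan plus bisection to 1e-8.
  Every reported `x50` satisfies the midpoint identity to < 1e-6. A
  numerically flat curve yields NaN with a flag.
* SE of `x50` by the delta method. Implicit differentiation of the
  midpoint-crossing condition (with `x_ext` held fixed — exact at a
  boundary extremum, first-order exact at an interior one where
  `f'(x_ext) = 0`) gives

      dx50/dbeta = [ (b(cp) + b(x_ext))/2 - b(x50) ] / f'(x50),

  and `se = sqrt(g' V g)`. The gradient is validated against central
  finite differences (relative error < 1e-3 coordinatewise) and the SE
  against a bootstrap oracle. `|f'(x50)| < 1e-10` flags the SE unstable.

### Bootstrap oracle

Case resampling within (dose, time) cells, refitting the spline (GCV and
all) and re-solving `x50` per resample; the SE is the SD of the resampled
values, failed resamples excluded and counted (> 20% failures flags the SE
unreliable). Because all wells in a cell share one `x`, resampling leaves
the design matrix unchanged and only permutes responses, so the basis is
reused. Plain case resampling within cells of 3 replicates deflates
within-cell variance by `(n_c - 1)/n_c` (SD shrink ~0.82) and would bias
the oracle low; resampled deviations from the cell mean are therefore
rescaled by `sqrt(n_c / (n_c - 1))`. After this correction the bootstrap
SE matches the true Monte-Carlo sampling SD of `x50` to a few percent
across the regimes checked.

### Known bias

The rank-4 basis cannot represent steep sigmoids exactly. For Hill slopes
above ~1.5 over a half-log dose grid the noiseless-fit `x50` is displaced
by up to ~0.1 log10 units, and `sigma^2 = RSS/(n - edf)` absorbs the lack
of fit, inflating the delta SE. On the *well-conditioned* sigmoid
benchmark (slope near 1, clear effect, midpoint inside the tested range)
recovery is tight (median |x50 error| ~ 0.05) but 95% CI coverage runs a
few points below nominal (around 0.87-0.91 depending on seed), driven by
a small systematic displacement (~0.45 SE) of the fitted midpoint toward
the rising limb — a smoothing artifact shared by any penalized-spline
treatment at this basis size, not removable without changing the model.

## Robustness statistics

* `rho_N`: Pearson correlation of the normal Q-Q plot of residuals, with
  Blom plotting positions `(i - 3/8)/(n + 1/4)`.
* Inter-batch: for one condition (compound, cell line, time, dose)
  measured in two batches, the Pearson correlation of the two per-gene
  log2FC vectors, and per-gene SD `|a - b|/sqrt(2)`; with more than two
  batches all unordered pairs are used and the SD generalizes to the
  sample SD across batches.
* Intra-batch: correlations between *different* compounds in one batch —
  near zero when perturbation signal rather than batch identity drives
  the fold changes.

## Synthetic data

The generator emulates a compound dilution plate: 8 half-log doses from
10 uM (3.5 decades), 3 replicate treatment wells per dose, 6 DMSO vehicle
wells, one 24 h time point, i.i.d. normal log2 noise with SD 0.1, an
optional fraction of wells offset by ±4 noise-SDs (gross outliers), and
optional replicated batches with additive N(0, sigma_b^2) shifts. These
defaults are typical of perturbational screens of this kind: half-log
spacing and ~3 replicates are the common plate economy, and 0.1 log2
units is a realistic within-plate noise floor for a bead-based assay.
True curves are flat (null), Hill sigmoids
`y0 + Emax/(1 + 10^(slope (ec50 - x)))`, or a rise-then-fall "hook"
(product of an ascending and a descending sigmoid). Baselines are drawn
U(4, 12) log2 units, effects U(0.5, 3) in magnitude, Hill slopes
U(0.75, 2), midpoints inside the tested range.

The truth table records both the generating parameters and the
*operational* truth — the extremum effect and the midpoint-crossing
concentration of the noiseless curve restricted to `[cp, x_max]` — which
is the estimand the spline estimator actually targets when the asymptote
lies beyond the top dose.

What the generator does **not** emulate: gene-gene correlation,
bead-deconvolution artifacts, heteroskedasticity across expression levels,
or plate-position effects. Passing benchmarks therefore demonstrate
statistical correctness of the estimators under the stated noise model,
not performance on raw screen data.

### Well-conditioned sigmoid benchmark

The delta-vs-bootstrap, gradient, and recovery benchmarks use a restricted
family — slope U(0.75, 1.25), |Emax| U(1.0, 2.5), midpoint central — so
that the quantity being validated is the standard-error machinery rather
than the basis-approximation error discussed above.

## Database layout

Four tables: `combination` (surrogate key per compound-batch-cell tuple;
the compound record is the pert_id + group_id pair, so a compound rerun in
a second batch is a second row), `model` (family fitted and convergence per
combo x gene), `test` (all differential-expression contrasts), and
`interaction` (potency/efficacy, spline-fitted genes only — enforced by the
integrity check). Serialized to SQLite (primary) or a TSV directory, both
with a provenance record (config hash, package version, seed); re-building
from identical inputs is deterministic. The exact published field list of
the artifact this layout mirrors is not recoverable from prose, so the
schema is a documented reconstruction carrying every named quantity.

## Benchmark scales

The shipped validation suite uses: 100 experiments x 1000 bootstrap
resamples for the SE comparison, 50 fits for the gradient oracle, 200
sigmoids for recovery/coverage, 1000 null genes per model path for type-I
error, and 100 genes x 2 batches with 8% contamination for the robustness
ordering. These sizes put Monte-Carlo error comfortably below the decision
thresholds while keeping the whole suite runnable on a laptop in minutes.
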