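# Methods

## Signal model

Scattered light measured through the transparent bottom of a continuously
shaken microtiter plate is a semi-quantitative biomass proxy: it rises
monotonically with biomass concentration but its absolute scale (arbitrary
units) depends on the device optics, the plate type and the filling
volume. The package models a trajectory with the extended sigmoid

    SL_fit(t) = a + b / (1 + exp(−(t − c)/d)) + e·t

a five-parameter family that interpolates continuously between a step
function (d → 0) and a nearly linear ramp (d large), which is exactly the
phenomenological range observed between too-strong induction (late,
step-like rise after an extended lag) and optimal induction (quasi-linear
rise). The model is descriptive, not mechanistic: no substrate, yield or
Monod-type kinetic parameters are identifiable from scattered light alone,
and none are claimed. Its two derived features are the inflection time `c`
and the closed-form inflection slope `SL_fit′(c) = b/(4·d) + e`.

Assumptions worth stating explicitly:

* one growth transition per well — diauxic shifts, oxygen limitation and
  evaporation drifts are not modelled;
* the non-induced reference well on the same plate experiences the same
  medium, temperature and measurement gain as the induced wells, so that
  the ratios `c_std = c/c_ref` and `slope_std = SL′(c)/SL′(c)_ref` cancel
  device and condition effects;
* measurement noise is approximately multiplicative (it scales with
  intensity), which informs both the simulator and the choice of fitting
  on the raw rather than log scale.

## Fitting

Nonlinear least squares (SciPy's bounded trust-region reflective solver)
with:

* initial guess a₀ = min(SL), b₀ = max − min, c₀ = time of the largest
  centered finite-difference slope, d₀ = (t_max − t_min)/10, e₀ = the
  least-squares slope of the final 20% of points floored at 0;
* bounds b ∈ [0, 10·(max − min)], d ∈ [10⁻³ h, t span],
  c ∈ [t_min − span, t_max + span], a and e free. The wide c bound lets
  the fitter place an inflection beyond the observation window (needed for
  strongly induced cultures whose rise is only beginning when monitoring
  ends); the d upper bound keeps the logistic identifiable against the
  linear term;
* five deterministic starts (the heuristic start and the four ±25%
  perturbations of (c₀, d₀)); lowest residual sum of squares wins, ties go
  to the smaller d. No random numbers are used, so fits are exactly
  reproducible;
* convergence at relative SSR change < 10⁻¹⁰ (and a step tolerance of
  10⁻¹²) within 2000 function evaluations; a curve for which no start
  converges yields a failure result (converged = False, R² = −∞), never an
  exception;
* the logistic and its derivative are evaluated through σ(x) and
  σ(x)·σ(−x), which stay finite where exp/cosh overflow (|t − c|/d up to
  and beyond 700).

Fits are kept only if they converged and R² > 0.96, with R² computed on
the raw scattered-light signal.

`e` is left unconstrained during fitting (only its initial guess is
floored at zero); whether a small negative drift term is physical is left
to the data.

### Identifiability caveat

When the trajectory is almost perfectly linear over the whole window —
possible for optimal induction with a very small inflection slope — the
inflection time is weakly identified: a saturated logistic plus linear
term fits as well as the true quasi-linear sigmoid, and the fitted `c` can
land outside the physical range (c ≤ 0). Standardization refuses such fits
with an explicit error; the pipeline reports those wells as
`indeterminate` with rule `non_physical_inflection` instead of guessing.
On the default synthetic plate this affects roughly 1–2% of optimal-regime
wells.

## SNV and PCA route

The standard normal variate transform centers and scales each trajectory
individually, SNV(SL(t)) = (SL(t) − mean)/std, using the sample (n−1)
standard deviation — the convention is pinned because exact-value tests
depend on it, although at ~448 points per curve the difference from the
population convention is negligible. SNV is applied on each culture's
native time grid first and only then interpolated (linearly, never
extrapolating) onto the common grid, because interpolation slightly
perturbs the mean and standard deviation. The default alignment window is
the intersection of all culture time ranges.

PCA is computed on the aligned SNV matrix with column mean-centering (SNV
centers rows, not columns) and no column scaling (all columns are already
on the SNV scale), i.e. covariance PCA. Each loading vector is sign-fixed
so its largest-magnitude entry is positive; scores flip accordingly. Two
components are retained by default; the stored explained-variance spectrum
always covers all components and sums to 100%.

PC1 score bands (defaults: insufficient below 2, too strong above 4) are
deliberately exposed as configuration: score scales are a property of the
dataset that defined the components, so the defaults must not be read as
universal constants. This whole route is retained for comparison; the
standardized-feature route is the recommended, transferable one.

## Classification rules and the indeterminate class

The rule regions in the (c_std, slope_std) plane do not tile the plane:
there is a gap between the optimal upper edge (1.9) and the too-strong
edge (2.0), and a region with slope_std < 0.25 but c_std < 1.1. Rules are
applied in fixed precedence (too strong, optimal, insufficient) and
anything unmatched is labelled `indeterminate` — an explicit "don't know"
was preferred over silently extending a neighbouring region. Non-induced
wells are behaviourally a special case of insufficient induction and are
reported as `insufficient` with rule tag `non_induced`. When several
replicate reference wells are available their features are aggregated by
the median, which tolerates a single failed well.

## EP model

Measured expression (final reporter fluorescence or an offline enzyme
activity endpoint) is min–max standardized within one dataset grouping —
different products, temperatures and assays are not comparable on the raw
scale, so EP = (x − min)/(max − min) is always per dataset. The predictive
response surface over the two standardized features uses the fixed term
set (1, c, c², s, c·s); the s² term is excluded by design. Default
coefficients are (0.76, 0.37, −0.14, −1.14, 0.27); `refit_ep_model`
re-estimates them by OLS (requiring n ≥ 10 and a full-rank design) and
reports the training R² and n. Predictions are returned both raw and
clipped to [0, 1], since the measured quantity lives in [0, 1] by
construction but the polynomial is unbounded.

## Synthetic plates

The simulator generates trajectories from the extended sigmoid itself —
the package tests its estimator, and the model class is the one asserted
to describe real curves — rather than from a mechanistic growth model.
Defaults define the study conditions used throughout the tests:

* grid: 448 points at a 6-minute cycle (0–44.7 h);
* reference parameters a = 2 a.u., b = 40 a.u., c = 15 h, d = 2 h,
  e = 0.2 a.u./h (inflection slope 5.2 a.u./h);
* regime boxes in (c_std, slope_std), strictly interior to the decision
  regions so that round-trip classification is unambiguous at the test
  noise level: insufficient [0.80, 1.05] × [0.60, 1.40]; optimal
  [1.15, 1.85] × [0.05, 0.24]; too strong [2.05, 3.50] × [0.30, 1.20];
* hub: the optimal regime reduces b to 60% of the reference (strong
  expressers form less biomass); other regimes keep the full hub; e is
  held at the reference value, and d is solved from the drawn slope
  target, d = b/(4·(slope_std·slope_ref − e)), so the drawn features are
  realized exactly;
* noise: multiplicative Gaussian with CV 0.02 on the signal and additive
  Gaussian with sd 0.10 on the observed EP. No device noise magnitudes are
  published for this class of instruments; these are stated assumptions,
  exposed in the configuration, chosen as typical for well-maintained
  optical plate readers;
* randomness: each well consumes its own PCG64 substream keyed by
  (seed, well index), so a plate is bit-reproducible and appending wells
  never perturbs existing ones.

The default study plate is 1 reference + 3 × 50 induced cultures
(problem sizes chosen so the full pipeline — 151 fits of 448-point curves
— runs in well under a minute on one core); the EP-refit checks use
n = 600 feature draws. What passing tests on these plates demonstrate is
that the estimator chain is correct and stable under the model's own
assumptions with realistic noise; they do not demonstrate robustness to
real-data features the simulator omits (diauxic shoulders, oxygen
limitation, well-to-well gain drift, evaporation, outlier wells).

## Known limitations

* The method gives no absolute recommendation for inducer concentration or
  induction time — only the direction (more/earlier vs less/later) implied
  by the regime label.
* Non-induced and insufficiently induced cultures are not distinguishable
  from the trajectory alone.
* PC score bands do not transfer between datasets without re-deriving the
  components.
* The EP surface is empirical; far outside the feature ranges it was built
  on, its raw predictions leave [0, 1] and only the clipped value is
  meaningful.
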