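# Methods

This note documents the models, numerical methods and defaults implemented in
burstfish, the assumptions behind them, and what the synthetic-data tests do
and do not demonstrate.

## The two-state (telegraph) model

A promoter alternates between OFF and ON states with rates `k_on` (OFF→ON)
and `k_off` (ON→OFF); transcripts appear at rate `k_prod` while ON and each
degrades independently at rate `delta`. All rates are handled as
dimensionless ratios to `delta`, so one time unit is one mRNA lifetime;
`to_absolute_rates` converts to per-minute rates given an mRNA half-life
(`delta = ln 2 / t_half`). The stationary count law is the Poisson-Beta
mixture, equivalently the Kummer-function form: the auxiliary variable
`x ~ Beta(k_on, k_off)` is the fraction of recent time spent ON, and the
count is `Poisson(k_prod * x)`.

Closed-form moments used for truncation and initial guesses:
`mean = k_prod*k_on/(k_on+k_off)` and
`var = mean + k_prod^2*k_on*k_off/((k_on+k_off)^2*(k_on+k_off+1))`.

The model is stationary: cells are assumed to have expressed long enough
(several mRNA lifetimes) for the count distribution to equilibrate.
Time-dependent solutions and three-state extensions are out of scope.

### PMF evaluation

`telegraph_pmf` integrates the mixture on a tanh-sinh (double-exponential)
grid in log space. The change of variables folds the Beta density *and* the
Jacobian into a single exponent carrying `x^k_on * (1-x)^k_off`, so nothing
blows up at the endpoints for any positive shape parameters (including the
sub-unity `k_on = 0.19` regime). The step starts at
`min(0.05, 1/(3.5*sqrt(k_prod)))` — interior integrand features have width
~`1/sqrt(k_prod)` in relative terms — and is halved until successive grids
agree entrywise within 1e-12; the grid cutoff is placed where the smallest
shape parameter has pushed the integrand below exp(-40). Probabilities as
large as `k_prod ≈ 1500` with counts in the thousands evaluate without
overflow or cancellation.

Two independent cross-checks guard the evaluator:

* `poisson_beta_oracle`: scipy adaptive Gauss-Kronrod (`quad_vec`) after
  splitting the integral at x = 1/2 and desingularizing each half with the
  substitutions `u = x^k_on` and `v = (1-x)^k_off`.
* `telegraph_pmf_hypergeometric`: the direct Gamma/1F1 form through the
  Kummer transform `1F1(a, b, -lam) = e^-lam 1F1(b-a, b, lam)`, whose series
  has all-positive terms; valid for `k_prod <= 600` where `e^lam` is
  representable.

The three paths agree entrywise to better than 1e-10 in the tests.

**Truncation.** The default bound is `n_max = k_prod + 8*sqrt(k_prod) + 25`.
Because the count is a mixture of `Poisson(k_prod*x)` with `x <= 1`, it is
stochastically dominated by `Poisson(k_prod)`, so this bound caps the tail
below ~1e-9 for *every* switching-rate combination. A mean + 10 sd rule was
considered and rejected: for rare-burst parameters the count tail stretches
toward `k_prod` itself regardless of the mean, and the measured tail beyond
mean + 10 sd at (0.19, 5.1, 571) is 3.4e-5. Results whose requested `n_max`
leaves more than 1e-6 of mass carry a `truncated` warning flag.

**Bin probabilities.** Fitting needs bin-aggregated masses, computed as
Beta-mixtures of Poisson CDF differences (`gammaincc`) on the same tanh-sinh
grid: cost is (#edges × #nodes) independent of the count scale, which keeps
the optimizer objective at ~2 ms even for wild-type-scale parameters. Bin
edges are mapped to integer boundaries with ceil. Agreement with summed PMF
entries is better than 1e-9.

### Sampling

`sample_counts` draws `x ~ Beta`, then `Poisson(k_prod*x)`.
`sample_counts_with_state` draws the *joint* stationary (count, state) law
using the exact conditional decomposition: given ON the mixing variable is
`Beta(k_on+1, k_off)`, given OFF it is `Beta(k_on, k_off+1)`; mixing with
the stationary occupancy `p_on = k_on/(k_on+k_off)` reproduces
`Beta(k_on, k_off)` identically (checked in tests against both the analytic
conditional means and Gillespie simulation). All randomness flows through a
single numpy Generator per call; passing the same seed reproduces results
bit-for-bit.

`gillespie_telegraph` is an exact SSA over the four reactions (switching,
production, per-molecule degradation). Defaults: burn-in 10 lifetimes,
samples every 4 lifetimes (autocorrelation `e^-4 ≈ 0.02`, so samples are
effectively independent), initial state drawn from the stationary occupancy
with a Poisson-mean count. An event-budget estimate raises a resource error
before starting simulations that would exceed ~5e7 events.

The total-variation distance between an empirical sample and the exact PMF
has an irreducible noise floor: at 2e4 samples of the (2.7, 3.7, 50) law it
is 0.019 ± 0.002 (mean ± sd over seeds) even for perfectly iid draws.
Consistency checks at or below that resolution are statements about sampling
noise, not about the simulator.

## Constrained histogram fit

`build_histogram` bins counts with a named deterministic rule; the default
is Freedman-Diaconis width rounded to an integer ≥ 1, widened if necessary
to keep at most 256 bins (and falling back to unit width when the IQR
collapses, as in mutant-like data dominated by zeros). Zero-count cells are
included: the model assigns them mass, and they are the denominator of the
active/inactive constraint.

`fit_two_state` minimizes the unweighted sum of squared differences between
observed bin frequencies and model bin probabilities over
`(log k_on, log k_prod)`, with `k_off = k_on/ratio` eliminated through the
nascent-cell ratio. Unweighted least squares is used deliberately (not
maximum likelihood): frequent bins carry the larger sampling variance, and
down-weighting them would put undue weight on the sparse tail. The search is
scipy `least_squares` (trf) inside bounds `k_on ∈ [1e-3, 50]`,
`k_prod ∈ [1, 10×max count]`, started from a method-of-moments guess plus
log-spaced multi-starts (8 by default); the best objective wins, ties broken
toward smaller `k_prod`. Fits that land on a bound are flagged unconverged
with a warning. A zero nascent ratio (no active cells) makes the constraint
degenerate and raises a boundary-fit error after warning.

`monte_carlo_errors` is a parametric bootstrap: `n_reps` synthetic datasets
of `n_cells` are drawn from the *fitted* law, the nascent tally is resampled
binomially at the fitted ON fraction, each replicate is rebinned with the
same rule and refitted (3 starts, seeded at the parent optimum), and the SEs
are the standard deviations of the refitted parameters. More than 20% failed
replicates marks the result unreliable. Calibration against fully
independent ground-truth ensembles puts the SE/SD ratio within [0.7, 1.4]
at 184 cells.

`goodness_of_fit` reports a reduced Pearson chi-square: adjacent bins are
pooled left-to-right until each pooled bin expects ≥ 5 cells (a trailing
remainder merges into its neighbour) and the statistic is divided by
(pooled bins − 2 free parameters − 1). Exact chi-square constructions vary
between analyses (binning, pooling, reduction convention all matter), so
this statistic is for *relative* model assessment — true-model fits
calibrate near 1, misspecified Poisson fits of bursty data score an order
of magnitude worse — not for matching any particular published value.

Burst metrics follow the standard telegraph definitions
(`frequency = k_on*k_off/(k_on+k_off)`, `size = k_prod/k_off`);
`compare_fits` reports reference/comparison ratios with direction labels
("reduction" = comparison below reference) and folds ≥ 1.

## smFISH quantification

Preprocessing follows blur → rolling-ball background subtraction →
z-binning, in that order. Defaults: Gaussian blur radius 1 px, rolling-ball
radius 50 px, z-bin 7 (e.g. 21 planes → 3). The rolling ball is the
classical morphological background estimator (scikit-image implementation);
its intensity semi-axis makes it only approximately equivariant to global
intensity rescaling, but because the transcript count is the *ratio* of a
cell's integrated intensity to the single-transcript calibration, the
residual effect cancels to sub-percent level.

Single transcripts and nascent sites are fitted as elliptical 2D Gaussians
plus a constant background (trust-region least squares; integrated intensity
`2π·A·σx·σy`); widths pinned at bounds, non-convergence or non-positive
amplitude set `ok=False` and downstream consumers skip the spot. The
calibration is the mean integrated intensity of accepted single spots (with
its CV); transcripts per cell is the thresholded per-cell integrated
intensity divided by that mean, reported as a real number by default (the
fit aggregates the PMF over bins, so fractional counts are unproblematic);
nascent RNA counts divide the nascent-site fit by the same calibration.

Crystal cells are gated by Otsu's threshold on log marker intensity (the
marker channel is bimodal: high in crystal cells, low elsewhere); a manual
threshold override exists, an all-equal marker degenerates with a warning.
The nascent detection threshold defaults to 3× the single-transcript
intensity — nascent sites are multi-RNA foci, but there is no standard
numeric visibility criterion, so the factor is exposed in configuration.
Cell segmentation is intentionally out of scope (outlines are typically
drawn manually in this protocol); label masks or pre-integrated tables are
accepted.

## Nucleosome relative shift

`relative_shift` implements the −log2 ratio-of-ratios of band read counts
against the motif-free 601 control, normalized by the no-protein input lane,
for either the free-nucleosome band (depletion) or the super-shifted band
(gain). A pseudocount (default 1) is added to every count because the
statistic is undefined at zero reads; exact-arithmetic checks use
pseudocount 0. The control's shift is pinned to exactly 0. The statistic is
invariant to per-lane depth rescaling and additive in composed depletions.
`summarize_titration` reports per-template maximum shift, its lane, and a
Spearman monotonicity score across the concentration series. The default
template registry models ten motif-position variants (superhelix locations
R0 through R8 plus two double-motif constructs) and the 601 control, but
arbitrary template sets are accepted.

## Synthetic data

The generators produce every input the analysis consumes, with ground truth
retained for assertions. Defaults are the study conditions: wild-type
(2.7, 3.7, 1524) with 184 crystal cells and mutant (0.19, 5.1, 571) with
340, plus an equal number of non-expressing background cells
(`background_fraction = 0.5`). Cell intensities are
`count × single-transcript intensity × lognormal noise` with CV 0.15 —
large enough to stress the calibration without breaking recovery — and the
single-transcript intensity is 10 units with spot-to-spot CV 0.2. The marker
channel is a two-component lognormal (means 100 and 1, log-sd 0.35), which
is separable by construction. The nascent site is rendered iff the promoter
is ON (the analysis equates visible nascent sites with the active state; a
lag parameter is reserved but defaults to 0), with a load of
4 + Poisson(4) RNAs so that it clears the 3× detection threshold.

Spot images are sums of elliptical Gaussians over constant or gradient
backgrounds with Poisson or Gaussian noise; band counts allocate each lane's
depth multinomially over (template, band) cells with planted occupancies,
the input lane pinned to occupancy 0.

What the synthetic tests show: the estimators recover planted truths under
the model's own assumptions plus realistic multiplicative intensity noise.
What they do not show: robustness to segmentation errors, optical crowding
and diffraction-limited spot overlap in dense cytoplasm, z-dependent
attenuation, probe-binding variability, or cell-to-cell degradation-rate
differences — none of which the generators emulate.

## Study-scale checks and problem sizes

The test suite runs the analyses at the sizes a desk machine handles in
minutes: PMF/oracle agreement over a 36-point parameter grid; Gillespie
consistency at (2.7, 3.7, 50) with 2e4 samples; recovery of wild-type
parameters in 100 replicates of 2000 cells (k_prod within 5%, k_on within
15%); fold-change recovery at the study's own 184/340 cells, where the
single-experiment estimate is noisy (the mutant activation rate carries a
~60% relative SE at that size) and the pipeline's point estimate is defined
as the median over replicate experiments; and bootstrap-SE calibration
against a 200-dataset ground-truth ensemble. Mutant-parameter recovery at
the 5% level is not asserted anywhere: at the study's own sample sizes the
mutant production rate is determined only to ~36% (and ~15% even at 2000
cells): with so few actively transcribing mutant cells, burst-size
conclusions in that regime are inherently soft.

## Known limitations

* The fit assumes steady state and a single shared degradation rate; slow
  approach to equilibrium or genotype-specific mRNA stability would bias
  the inferred switching rates.
* The chi-square reduction convention is one of several; absolute values
  are not comparable across analyses with different binning.
* The hypergeometric cross-check path is limited to `k_prod <= 600`.
* The Gillespie sampler is a plain Python loop — exact but not tuned for
  event counts far beyond ~1e7.
* Relative shifts with pseudocount > 0 are slightly biased toward 0 at low
  depth; use deeper simulated counts or pseudocount 0 when counts permit.
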