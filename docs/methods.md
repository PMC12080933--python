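# Methods

## The decision-variable model

All estimators in this package operate on one generative model of a 2IFC
disparity-discrimination trial. The observer forms disparity estimates for
the comparison and standard stimuli; their difference is the decision
variable

    D = Δδ + V + W,    Δδ = δ_cmp − δ_std,

with a stimulus-driven perturbation `V ~ N(0, σ_E²)` set by the particular
stimuli of the trial and internal noise `W ~ N(0, σ_I²)` drawn fresh on
every presentation. The comparison is chosen when `D` exceeds the
criterion, assumed zero (justified by the symmetric two-interval design).
All variances are in arcmin². Assumptions: `V` and `W` independent and
normal; variance constant across the comparison levels of a condition;
criteria equal across passes. The model is applied separately to every
(pedestal, disparity-contrast-bin) condition.

Stimulus perturbations attach to the *unique trial* (the
standard/comparison pair), not to individual stimuli: the decision
variable only ever sees the trial's difference, so a finer decomposition
would not be identifiable from binary responses.

### The √2 convention

Two d′ conventions coexist in the signal-detection literature for 2IFC.
The per-interval convention writes `PC = Φ(d′/√2)`; the decision-variable
convention writes `PC = Φ(Δδ/σ_T)` with `σ_T` the SD of `D`. They differ
by √2 depending on whether σ refers to one interval's estimate or to the
difference. This package is internally consistent in the *decision
variable*: the psychometric function fitted to choices is
`Φ((δ_cmp − δ_std)/σ_T)`, the fitted sigma is `σ_T`, the normalized means
entering all orthant likelihoods are `Δδ/σ_T`, and the simulator's choice
rates converge to `Φ(Δδ/σ_T)`. `pc_from_dprime` keeps the textbook
per-interval form `Φ(d′/√2)` so that the criterion `d′_crit = 1` sits at
the 76% point of the psychometric function — the conventional definition
of threshold-level performance — and `T = σ_T · d′_crit`, giving
`T² = σ_T²` at the default criterion.

## Psychometric fitting

Per-condition fits maximize the Bernoulli likelihood of the binary
choices under a cumulative Gaussian; mean and sigma are free, or the mean
is pinned at the standard disparity (the generative model is unbiased).
Degenerate data are flagged, not raised: a fit is labeled `sigma_floor` /
`sigma_ceiling` when the likelihood at the corresponding sigma bound comes
within 0.25 nats of the optimum, i.e. when the data cannot distinguish
the fit from a step function or from chance.

Across the five pedestals of a bin, thresholds are constrained to the
log-linear law `σ_T = exp(m·δ_std + b)` (pedestals kept signed, negative =
uncrossed, matching the study's convention). The two line parameters are
fit by joint ML over all pedestals (Nelder-Mead, multi-start from a
probit-regression initializer, log-likelihood tolerance 1e-8). The
constrained fit is nested in the per-condition fits, so its likelihood
never exceeds their sum — a property the tests check. Thresholds entering
the correlation estimators are *frozen* from these constrained fits rather
than re-estimated jointly with ρ; this mirrors the two-stage design of the
analysis and keeps the orthant likelihood a function of correlations only.

## Orthant probabilities

The likelihood of a joint response pattern is the mass of a multivariate
normal orthant. Requirements: deterministic (the optimizer must see a
smooth, repeatable surface), absolute accuracy 1e-6 (2-D) / 1e-5 (4-D),
and ~1e5 evaluations per bootstrap run. Three routes:

* **2-D**: closed form via Owen's T function, with explicit limits for
  zero arguments and |ρ| → 1. Near machine precision.
* **4-D, two-group structure** `[[1,a,c,c],[a,1,c,c],[c,c,1,b],[c,c,b,1]]`
  (the only structure the pass-pair analyses produce): conditioning on a
  single shared Gaussian factor with loadings `λ_f λ_n = c` decorrelates
  the two pairs, leaving a product of bivariate orthants integrated over
  one dimension by Gauss-Hermite quadrature (48 nodes by default; 32 in
  bootstrap refits). The loading split `λ_f² = |c|·√((1+a)/(1+b))` keeps
  both residual pair correlations inside [−1, 1] over the entire
  positive-semidefinite region, which is exactly
  `(1+a)(1+b) ≥ 4c²` (and `a, b ≤ 1`). Verified against Monte-Carlo
  oracles to ≲1e-6; with equal means within a pair the integrand reduces
  to a single Owen's-T call per node, which is what makes the ML fits and
  bootstrap affordable.
* **4-D, general PSD matrix**: Genz-style sequential sampling on a
  scrambled Sobol sequence with a fixed seed; eight independent scrambles
  give an error estimate and the sample count doubles until 3.5·SE meets
  the tolerance. Near-singular matrices are floored in the eigenvalue
  domain with a warning.

Pattern order is frozen for I/O: binary counting with `−` = 0, `+` = 1,
first pass most significant (`--, -+, +-, ++`; sixteen analogously).

## Correlation estimation

Counts of response patterns per comparison level are multinomial with
orthant-probability rates. Levels of a condition share one ρ (or one
triple) and contribute level-specific normalized means; the summed
multinomial log-likelihood is maximized with ρ searched through an
inverse-hyperbolic-tangent reparameterization (bounds |ρ| ≤ 1 − 1e-6).
Levels at proportion 0 or 1 are retained — they constrain ρ only weakly
but are not excluded. The quadruple-pass fit runs Nelder-Mead from a warm
start assembled from pairwise two-pass estimates (cross-pair start clipped
into the PSD region), with cold restarts at (0.3, 0.3, 0.2) and the origin
if the warm start fails; PSD violations are rejected by a growing penalty.
The normalizing SD vector is `(σ_T†, σ_T†, σ_T*, σ_T*)`, matching the 4×4
correlation matrix.

The interaction-free mode pins `cov[L,B] = 0` by tying
`ρ†* = ρ†† · σ_T†/σ_T*`, removing one free parameter. The between-observer
estimator is the same fit with pass pairs (obs1-p1, obs1-p2, obs2-p1,
obs2-p2) inside one experiment; the partial correlation `ρ₁₂/√(ρ₁₁ρ₂₂)`
is clamped to [−1, 1] with a flag when the raw value escapes (possible for
degenerate or duplicated data, where ρ₁₂ sits on the PSD boundary).

## Variance partition

Closed-form algebra converts correlations and thresholds into components;
the forward and inverse maps are exact inverses (round-trip tested to
1e-12) and conservation `σ_E² + σ_I² = σ_T²` holds identically. Sampling
error can make σ_L², σ_B² or the internal-noise variances algebraically
negative; they are reported raw with flags, never clipped — the sanctioned
remedy is the interaction-free refit. Threshold-style summaries report
SDs (√variance) alongside variances, since SDs are what threshold plots
show while variances are what add.

## Bootstrap

The resampling unit is the unique trial with all of its passes and its
cross-experiment partner, resampled with replacement within each
(pedestal, bin, comparison-level) cell so the design layout is preserved.
Because every estimator depends on the data only through per-cell pattern
counts, the trial-level bootstrap is realized as a multinomial resample of
those counts; each resample re-runs the constrained threshold fits and the
quadruple-pass fits, warm-started at the point estimates with relaxed
optimizer tolerances (parameter tolerance 1e-3, likelihood tolerance 0.01
— far below the width of any interval). Intervals are percentile. Default
200 resamples for routine runs; the generic `bootstrap_ci` accepts any
estimator of trial records for quantities outside this fast path.
Block-level resampling is not supported: block membership is not part of
the trial schema, and trial-level resampling is the finer-grained choice.

## Synthetic data: what it emulates, what it does not

The generator reproduces the study design exactly: 5 pedestals
(−11.25 … −3.75 arcmin, uncrossed) × 2 disparity-contrast bins × 5
comparison levels × 100 repeats = 5000 unique trials per experiment,
two experiments × two passes = 20,000 presentations per observer, with
stimulus perturbations shared across passes (and across experiments for
the luminance component) exactly as the decision-variable model demands.
Comparison levels are symmetric about — and include — the standard;
spacing defaults to placing the outer levels at the 10%/90% points of the
generative psychometric function, the placement a practitioner would
choose from pilot data. Interval order is randomized per unique trial and
held fixed across passes (it does not enter any likelihood). Generative
SDs follow log-linear pedestal laws with the depth component scaled down
~10× in the low bin — the regime the flattened/natural comparison was
designed to probe. The three simulated observers of the end-to-end tests
differ mainly in internal noise, the dominant between-observer difference
the methodology expects.

What passing tests on this generator do **not** show: that real decision
variables are Gaussian or criterion-stable, that real luminance and depth
perturbations are additive and trial-attached, or anything about serial
dependencies, lapses, or learning — none of which the generator contains.
The synthetic patches are likewise plumbing, not natural scenes: smoothed
Gaussian noise with an exactly-targeted disparity-contrast, sufficient to
exercise the metrics, flattening, vetting and I/O, but carrying no
natural-scene statistics. Loading the deposited human data is out of
scope; `read_trials` documents the CSV schema an adapter would target.

## Numerical and design choices

* Window convention: separable 2-D Hann profile peaked at the center
  pixel (`size // 2`), 32 px = 1°; a radial variant is available. Weber
  contrast normalizes each eye by its own windowed mean.
* Central-region membership (vetting, pillbox windows): pixel center
  within diameter/2, ties included; the largest window is defined as the
  whole patch.
* Half-occluded pixels are excluded from disparity-contrast with weight
  renormalization; flattening clears the half-occlusion mask (identical
  half-images have no monocular zones).
* Spatial-integration regression: "random effects conditioned on
  pedestal, bin and observer" is implemented as group-indexed intercepts
  and slopes in a single logistic fit (a fixed-effects rendering; an
  intercept-only grouping is a switch). Pseudo-R² is McFadden's, reported
  both against the intercept-only null (absolute) and the group-intercept
  null (incremental); AIC differences are taken against the central-pixel
  model. Quasi-separation falls back to a weak ridge penalty with a flag.
* Heuristic decision variables: "nearest" = maximum signed disparity
  (crossed = near), "farthest" = minimum, "max-deviant" = value with the
  largest absolute deviation from the central pixel, signed value
  returned.
* All simulation randomness flows from explicit seeds through
  `numpy.random.SeedSequence` substreams (stimulus perturbations; one
  noise stream per experiment), so pass-sharing is unambiguous and every
  artifact is reproducible byte-for-byte.
* Problem sizes in the end-to-end suites: twenty replicate experiments at
  the full study scale with 200-resample bootstraps for the recovery
  check; Monte-Carlo orthant oracles at 10⁶ samples. These sizes make the
  recovery and coverage properties statistically decisive while keeping
  the whole suite runnable on a laptop.

## Known limitations

* The orthant engine covers dimensions 2 and 4 only — the dimensions the
  pass designs need; no n-pass generalization.
* Criterion drift between passes and lapse rates are not modeled
  (the analyses assume, as the methodology does, stable zero criteria; a
  per-condition sign-rate symmetry diagnostic is the recommended check).
* The between-observer partial correlation inherits the PSD coupling of
  the joint fit: with nearly duplicated data ρ₁₂ rides the boundary
  `√((1+ρ₁₁)(1+ρ₂₂))/2` and the within-observer terms are biased upward.
* Negative algebraic variance components are possible under sampling
  error by construction; consumers should respect the flags rather than
  truncate.
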