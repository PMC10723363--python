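# Methods

This note documents the models implemented in `netcollapse`, the conventions
and numerical choices behind them, the design of the synthetic cohort
generator, and what the validation suite does and does not establish.

## Atrophy W-scores

Gray-matter atrophy is measured per region as a covariate-adjusted deviation
from a normative model.  For each region, gray matter in a reference cohort
is regressed on covariates (age, sex, scanner, ...); a subject's W-score is
`(predicted − actual) / residual SD`, where the residual SD comes from the
reference fit.  We adopt the atrophy-positive orientation — larger W means
more tissue loss than expected, and W > 1.5 is the conventional significance
threshold — with a flag (`atrophy_positive=False`) for the raw orientation.
Regions whose reference fit is exact (zero residual SD) are rejected with an
error rather than producing infinite scores.

## Gradient space

Gradients are principal components of temporally concatenated regional BOLD
timeseries from a normative pool.  Conventions:

- **Projection uses orthonormal eigenvectors.**  Eigenvalue-scaled loadings
  are kept separately as display maps (`display_loadings_`, scaled by
  √eigenvalue, or by the raw eigenvalue via `display_scale="eigenvalue"`).
  The covariance algebra below requires the orthonormal convention; any
  fixed column scaling cancels in correlations.
- **Sign convention:** each eigenvector's largest-|weight| region is made
  positive, so fits are reproducible across runs and libraries.
- **FC from gradient moments:** with basis `E` (R×K) and gradient covariance
  `Σ` (K×K), region covariance is `E Σ Eᵀ`; correlations follow from its
  diagonal.  At K = R this equals direct Pearson FC to ~1e-15 (verified on
  100 random instances).  Regions with zero implied variance are flagged and
  set NaN, never silently zeroed.
- Covariance uses the unbiased (n−1) estimator throughout.  Gradient scores
  enter covariance unstandardized by default.
- **Edge vectorization:** row-major upper triangle, i < j, diagonal excluded
  (30135 edges for 246 regions); covariance flattening includes the diagonal
  (30381 entries).
- **Variance partition:** the share of a subject-level score attributable to
  each of the 21 gradient moments (6 variances + 15 covariances) uses
  LMG-style hierarchical partitioning — the average over random predictor
  orderings (default 200, seeded) of each term's sequential R² increment —
  because sequential shares depend on ordering and no single ordering is
  privileged.  Collinear moment sets trigger a condition warning and a small
  ridge on the normal equations, recorded in the output.

## Structure-function components

PLSR decomposes atrophy (X, the grounding side, chosen for its stronger
spatial hypotheses and lower measurement variability) into components that
maximally covary with FC edges (Y).  The implementation is NIPALS PLS2 with
deflation (scikit-learn's `PLSRegression`); columns are centered but not
variance-scaled by default, since W-scores and FC edges are already on
comparable scales (a `scale=True` flag exists).  Per component we report
paired structure/function loadings, per-subject scores, the score
correlation, and the fraction of atrophy variance carried.

**Split-half reliability** rebuilds the PLSR independently in label-balanced
half-cohorts.  Component order and sign can swap between halves, so halves
are matched by maximum-|correlation| assignment (Hungarian algorithm on the
absolute loading-correlation matrix) before recording per-component |r|;
the assignment is returned.  The reliability cutoff is the analyst's choice;
the module reports full distributions.

**Ridge function scores** avoid the circularity of PLSR scores in
cross-validated prediction: atrophy components are re-derived by PCA on
atrophy alone (their loadings correlate with the PLSR structure loadings at
|r| > 0.95 on planted cohorts), then ridge regression (α = 1000, 4
label-stratified folds, several shuffled trials) predicts each atrophy score
from FC edges.  A subject's function score is taken only from folds where
the subject was held out, averaged over trials, so downstream models can use
structure and function scores as de-correlated predictors.  Shuffling
test-fold FC rows relative to atrophy destroys the out-of-fold correlation,
which is the no-leakage check in the test suite.

Typical-syndrome subsets use LDA on the component scores (a subject is
"typical" when classified into its own label); the two-dimensional cohort
map uses classical (Torgerson) MDS — double-centered squared-distance
eigendecomposition — with the embedded-vs-input distance correlation
reported.  scikit-learn's MDS is SMACOF, not classical, so this ~15-line
routine is implemented directly.

## Coupled-oscillator model of gradient dynamics

Each gradient's second derivative is regressed on all gradients' positions
and velocities plus an intercept (2K+1 terms per equation; 13 at K = 6).
Derivatives are central finite differences on the TR grid (one-sided at the
endpoints); all fitting is in TR time units, with Hz conversion only at
reporting (β/2π/TR).  Mixed-TR cohorts are handled per subject, never
resampled.

Numerical points that matter:

- **Finite-difference bias.**  The truncation error of the second-difference
  grows ~ω²/12 relative to the signal; position coefficients of fast
  gradients (ω ≳ 0.3 rad/TR) carry a few-percent deterministic bias, and
  couplings smaller than ~ω⁴_max/12 are below the bias floor.  Recovery
  studies therefore use slow planted systems (ω ≤ 0.14 rad/TR).
- **Endpoint rows.**  The one-sided endpoint differences have O(h) error,
  which the second differencing propagates one row inward; on clean data
  these four rows can dominate the bias of small coefficients.
  `drop_endpoints` excludes rows from the regression (the default keeps
  them, matching finite differencing of the full series; recovery studies
  use `drop_endpoints=2`).
- **Stochastic data.**  On noise-driven series the regression residual is the
  forcing itself; damping estimates are attenuated (an errors-in-variables
  effect inherent to the estimator).  Absolute damping values from such fits
  should be read as biased; all cohort-level analyses here are correlational
  and unaffected.

The state matrix is the companion form `A = [[0, I], [P, V]]`; its position
rows are exactly [0 | I] and its spectrum equals the quadratic eigenproblem
roots of the second-order system (checked against an independent
linearization).  Fitted intercepts shift the affine fixed point
`−A⁻¹[0, β₀]`; simulation operates on deviations from it and adds it back.

**Eigenmodes.**  Conjugate pairs are collapsed keeping β ≥ 0; real
eigenvalues are retained individually and flagged overdamped.  Modes are
sorted by ascending frequency.  Gradient components are read from the
position rows of each eigenvector.  The eigenvector gauge is fixed by
normalizing the position subvector to unit modulus-norm and rotating so
gradient 1's component has phase 0 (largest-amplitude gradient if gradient 1
is silent below 1e-8).  Near-degenerate eigenvector matrices (condition
number > 1e8) are flagged; generalized-eigenvector handling is not
implemented — such fits are rare for noisy data and are excluded with a
recorded reason.

**Mode excitation weights.**  Eigenvectors alone carry no information about
how strongly the data excited each mode — any per-mode rescaling is a valid
gauge.  When a trajectory is attached (`resolve_weights`, the default on
`fit`), the observed states are decomposed onto the raw eigenvectors and
each mode's weight is the rms modulus of its coefficient timeseries, scaled
by the raw position-subvector norm and doubled for conjugate pairs.  The
product `weight × |component|` is gauge-invariant and equals the mode's
physical contribution to that gradient's signal; this is what makes planted
amplitude scalings exactly recoverable.

**Simulation.**  Closed-form trajectories evaluate `V e^{Λt} V⁻¹ Y₀`;
numerical trajectories use classical RK4 with configurable substeps per TR
(50 substeps keeps the two within 1e-6 over 500 steps on random stable
systems).  An overflow guard rejects horizons where a positive eigenvalue
would grow by more than e⁵⁰.  Subject-level simulated FC follows the
ensemble convention: one trajectory per observed timepoint's (position,
velocity) state, each run for the scan length, per-trajectory region FC
averaged; a `single` mode uses only the first state.  The two agree well
when trajectories are quasi-stationary (light damping); under heavy damping
the single readout depends on the first state's modal mix.  A fitted system
whose largest eigenvalue would grow by more than e⁵ over the horizon falls
back to a single short-horizon simulation with a logged warning.

## Collapse metrics

- **Cumulative amplitude** of gradient g: `Σ_m w_m √((b−a)² + (a+b)²)` over
  modes, with `a + ib` the gauge-normalized component and `w_m` the mode
  weight.  The per-mode term equals `√2 |a+ib|`; the constant is immaterial
  because all uses are correlational, but the printed form is implemented
  as stated.
- **Pairwise phase angle:** per mode, `arg(a₁+ib₁) − arg(a₂+ib₂)` wrapped to
  (−180°, 180°], then averaged on the circle with weights proportional to
  the product of the two gradients' per-mode amplitudes (normalized per
  subject); overdamped modes participate with their real components.
  Wrapping happens per mode, before the weighted mean.  90° means the
  gradients oscillate in temporal quadrature (uncorrelated); the correlation
  of two gradients sharing one dominant undamped mode equals cos(angle)
  (verified to 0.03).
- **Folding.**  Cohort tables fold angles to [0°, 180°] (`|angle|`).  The
  covariance content of an angle lives in its cosine, which the fold
  preserves, while the sign of the circular difference depends on which
  conjugate mode is kept and on the baseline quadrature direction —
  between-subject comparisons of the signed angle would mix that arbitrary
  sign with the effect of interest.  Per-subject signed angles remain
  available.
- The 21-element metric vector (6 amplitudes, then 15 angles in row-major
  pair order) is correlated column-wise against the matching moment vector
  (6 variances, 15 covariances) across subjects; the table's diagonal holds
  the corresponding entries.  Constant columns yield NaN and are excluded
  from the medians.

## Synthetic cohort generator

The generator's role is to plant the statistical structure the analysis
assumes, with every truth recorded.

**Dynamics by modal construction.**  Each subject's system is assembled from
its intended eigenstructure: mode k gets eigenvalue `−γ_k + iω_k` and an
eigenvector position part with unit weight on gradient k and modulus
`cross_amp` on every other gradient, whose complex phases encode the planted
pairwise angles.  `A = Re(W Λ W⁻¹)` then has exactly those modes, is stable
by construction, and is automatically companion-form (every eigenvector has
the shape `[v; λv]`).  Planting angles through the eigenstructure rather
than through calibrated coupling coefficients is essential: on a fixed
stable baseline, off-diagonal position coupling can move a pair angle only
~10° before an eigenvalue crosses zero, far short of the collapse range the
cohort needs.

Default conditions (chosen once, for identifiability and realism):

- `omega_range = (0.15, 0.45)` rad/TR → 0.012–0.036 Hz at TR = 2 s, inside
  the conventional 0.008–0.08 Hz BOLD band.
- `damping_ratio = 0.3`: short autocorrelation, so a 500-TR scan carries
  enough effective samples for stable moment estimates.
- `cross_amp = 0.15`: above ~0.2 the eigenvector matrix becomes strongly
  non-normal and the forcing gain varies wildly between subjects, drowning
  covariances in scale noise; below ~0.1 the cross components fall under the
  fitting noise.
- Forcing amplitudes scale as ω^1.5, equalizing mode excitation so
  high-frequency pairs remain identifiable (gradient 1 keeps a modest
  variance edge, preserving its first-component role).
- Pair angle targets are 90° + N(0, 20°) — a between-subject spread matching
  the reported 20th–80th percentile collapse range (93°→64°) — with the
  gradient-1/4 target shifted by `atrophy_phase_effect` (13°) per unit
  severity.  Each target's quadrature sign is randomized: the folded angle
  is sign-invariant, and random signs make the cross-mode contamination of
  every other pair's angle zero-mean instead of systematic.
- Amplitudes: per-gradient lognormal jitter (sd 0.2 on the log scale), with
  gradient 1 scaled by `1 − atrophy_amplitude_effect·severity` (0.25 per
  unit severity, so severity 2 leaves half the amplitude and a quarter of
  the variance).  The scaling is applied to the generated gradient
  timeseries — a coordinate change `S A S⁻¹` that leaves all planted angles
  and frequencies untouched.

**Integration.**  Trajectories are driven by white-noise forcing on the
velocity coordinates via Euler–Maruyama with an inner step of TR/10 and a
200-TR burn-in, so recorded series are stationary; fitting the deterministic
regression to noise-driven trajectories is exactly the estimation problem
the method faces on real data.  Total gradient variance differs < 20%
between halves of a 4000-TR run (the fastest mode's windowed variance
fluctuates more, partly an O(dt) discretization effect).

**Atrophy and behavior.**  Severity is uniform on [0, 2]; atrophy is
`s·global + f₂·focal₂ + f₃·focal₃ + noise` with an all-positive global map
and mean-centered (bipolar) focal maps, so mean atrophy tracks severity;
behavior scores are noisy linear combinations of (s, f₂, f₃).  `noise_sd`
scales the measurement-side noises (region residual after basis mixing,
atrophy residual, behavior residual); `forcing_sd` scales the process noise.

**Low-rank structure-function cohorts** (for PLSR/ridge validation) plant the
coupling directly: atrophy is a linear combination of a lognormal(0, 0.75)
global-severity map and exactly mean-zero focal patterns orthogonal to it;
FC edges are linear in function latents that correlate with the matching
atrophy factors at the planted r (default 0.6).  Factor scales
(2.4, 1.0, 0.7) mirror a dominant global factor over focal ones.  The
lognormal heterogeneity of the global map matters: split-half comparisons
correlate *centered* loadings, and a near-constant positive map would carry
almost no centered signal.

**What the generator does not emulate:** spatially structured measurement
noise, head-motion artifacts, scanner differences, hemodynamic convolution,
non-stationarities, nonlinear dynamics, and any coupling between focal
atrophy factors and dynamics (only severity perturbs the oscillator).
Passing recovery tests therefore establishes that the estimators invert the
planted generative structure — not that real data satisfy that structure.

## Validation studies and problem sizes

`netcollapse.validation` holds the recovery studies run by
`scripts/acceptance.py` and asserted in `tests/test_acceptance.py`:
FC-algebra equivalence (100 random 60×20 instances), oscillator parameter
recovery (planted slow K=6 system, 2000 TRs, RK4 fine integration),
closed-form vs RK4 agreement (20 random stable systems, 500 steps), phase
recovery at offsets {0°, 45°, 90°, 135°} with the cos-correlation identity,
amplitude-scaling recovery at {0.5, 1, 2} with FC monotonicity, PLSR
component and split-half recovery (300 subjects, 100 regions, 200 splits),
out-of-fold ridge validity (planted r = 0.6 and a null cohort), the 21×21
metric-moment correspondence (100 subjects), spectrum/trace conservation,
and the analytic edge counts for a 246-region atlas.

## Known limitations

- Damping estimates from stochastically forced data are biased toward zero
  (errors-in-variables); only deterministic trajectories support absolute
  damping recovery within tolerance.
- Pairwise angles of weakly excited gradient pairs are noisy; the
  cohort-level correspondence analysis, not single-subject angles, is the
  validated readout.
- The FC-outlier PCA flag marks ~16% of even clean scans by construction
  (> mean + 1 SD); it is a screening rule, not an error rate.
- Generalized eigenvectors (exactly repeated eigenvalues) are not handled;
  affected fits are flagged and excluded.
- ComBat site harmonization is an interface point only; synthetic cohorts
  are single-site and the pipeline warns rather than harmonizes.
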