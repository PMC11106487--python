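# Methods

This note records the models the package implements, the default
parameters and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical choices that matter.

## Pair-correlation analysis of localization data

### Estimator

`paircorr.compute_pair_correlation` bins localizations onto a 10-nm grid,
computes the 2D autocorrelation of the count image by FFT, divides by the
autocorrelation of the rectangular ROI mask (translational edge
correction; for a full rectangle this equals the separable closed form
`(nx−|dx|)(ny−|dy|)`, which is what the code uses) and by the squared mean
density, then averages radially onto 10-nm bins.  Bin centers are the
pair-count-weighted mean lag distances, which removes most of the grid
discretization bias.  The self-pair lag (0, 0) is excluded.  Curves are
normalized so the mean of g over the outer quartile of r bins equals 1;
the normalization target is a design choice — the tail of g is the natural
reference because every model here decays to 1.

Defaults: grid pixel 10 nm (well below the ~20-nm localization error), bin
width 10 nm, r_max 500 nm (beyond which the signal is flat at these
cluster sizes), ROI 4×4 µm.  An O(n²) pairwise estimator with the analytic
isotropized set covariance of the rectangle serves as the independent
oracle in the tests.

### Models and fitting

The random model `g(r) = 1/(4πσₛ²ρ)·exp(−r²/4σₛ²) + 1` describes isolated
molecules observed with blinking: repeated localizations of one molecule
differ by two independent localization errors, hence the Gaussian of
width √2·σₛ; the fitted ρ is an *effective* density absorbing the
blinking-multiplicity statistics.  The clustered model adds the molecular
correlation `A·e^(−r/ξ) + 1` convolved (2D) with the unit-mass Gaussian
localization-error kernel.

The convolution is evaluated by an exact radial quadrature: for radial f,
`(f ⊛ K)(r) = ∫ f(s)·s/s_g²·exp(−(r−s)²/2s_g²)·I₀e(rs/s_g²) ds` with
`s_g² = 2σₛ²`, discretized at `ds = s_g/24` (unit-mass error < 5·10⁻⁴).
An explicit 2D grid-FFT convolution is retained as `method="grid"` and the
two routes are pinned equivalent (< 1%) in the tests; the radial route is
the default because it is smooth in the parameters and ~100× cheaper
inside the optimizer.

Fits are bounded least squares on the normalized curves over 10–500 nm,
unweighted residuals, with A, ρ, ξ optimized in log space.  The clustered
fit uses multistart over ξ ∈ {25, 50, 100} nm plus an A ≈ 0 start; the
best-MSE solution wins.  MSE is the mean squared residual over the fit
range.

### σₛ: reference estimate, not per-ROI self-fit

The clustered fit freezes σₛ.  Estimating σₛ by fitting the random model
*to the same clustered curve* does not work: the free Gaussian absorbs the
cluster peak (σ̂ₛ ≈ 34 nm for a true 20 nm at the default ground truth),
after which no member of the frozen-σₛ clustered family fits the data and
the classification collapses.  The package therefore estimates σₛ from an
isolated-molecule reference condition — random-model fits to CSR reference
ROIs, pooled by averaging — and holds that value fixed in all clustered
fits of the experiment (`sigma_mode="pooled"`).  Per-ROI self-estimation
remains available (`sigma_mode="per-roi"`) and is harmless for conditions
that are actually random.

### Classification and size comparison

Per condition (≥ 8 ROIs) the two per-ROI MSE samples are compared with a
two-sample KS test; p ≤ 0.05 ⇒ clustered, else random.  Error samples that
are numerically indistinguishable (within 10⁻⁶ relative) are treated as
ties → random.  Cluster sizes are reported as diameters `2ξ̂` only for
clustered verdicts; two clustered conditions are compared with an unpaired
two-sided rank-sum test.  The 2ξ diameter convention is applied
symmetrically by the generator and the reporter, so recovery statements
are independent of the convention.

## Synthetic localization data

Molecules are either completely spatially random (Poisson) or drawn from a
shot-noise Cox (parent–offspring) process.  For the exponential target
correlation `1 + A·e^(−r/ξ)` the offspring kernel is constructed
numerically: its radial Fourier (Hankel) transform is the square root of
the target pair-density transform, `f̂(k) = (1+(kξ)²)^(−3/4)`, and the
radial CDF is tabulated as `F(R) = R·∫ f̂(k)J₁(kR) dk` (absolutely
convergent; the kernel density itself has an integrable r^(−1/2)
singularity at the origin) and sampled by inverse CDF.  Parent intensity
`κ = 1/(2πξ²A)` and offspring mean `density/κ` give amplitude A exactly.
The construction is validated in the tests against the closed form of the
kernel, `f(r) ∝ (r/ξ)^(−1/4)·K_{1/4}(r/ξ)`, and against brute-force pair
histograms of generated molecule positions (within a few % of the target
over 20–200 nm).  A Gaussian (Thomas-process) kernel mode is also
provided.  A = 0 degenerates to the CSR generator.

Blinking: each molecule emits k ≥ 1 localizations, k geometric with mean 3
(configurable); each localization is displaced by isotropic Gaussian noise
of SD σₛ = 20 nm per axis; points leaving the ROI are discarded.  The
geometric law is the conventional overcounting model; its exact shape only
rescales the fitted effective ρ.  Default molecule density 600/µm² yields
~1800 localizations/µm², inside the 1,300–5,000/µm² range typical of the
experiments emulated.  Not emulated: raw camera frames and PSFs, drift,
axial structure, frame-correlated blinking (frame indices are assigned at
random), detection inhomogeneity.  Passing recovery tests therefore shows
the *analysis chain* is unbiased for patterns with the assumed statistics,
not that real acquisitions satisfy those assumptions.

## Number & brightness

Per pixel and frame the fluctuating-species count is Poisson (fast
exchange between frames), an n-mer emits n·ε photons/dwell on average, and
detection is Poisson (optionally scaled/offset plus Gaussian readout noise
for the analog chain).  This gives exactly B = 1 + ε·Σfₙn²/Σfₙn and B = 1
for immobile (constant-rate) structures.  Detector calibration fits the
series-averaged ⟨Var⟩ vs ⟨I⟩ line (slope S, intercept q; |r| ≥ 0.99
required), estimates σ₀ from the dark-count histogram's half-maximum width
(zeroed below 0.1) and derives the offset as (σ₀² − q)/S.

Detrending subtracts a centered moving-average trend (default window 10 of
50 frames, edges shrink the window), recenters the residuals, rescales
them so the expected sample variance of stationary white noise is exactly
preserved, and adds back the pixel mean.  The rescale factor is computed
exactly from the high-pass's linear map (`tr(MᵀCM)/(T−1)`); a naive boxcar
high-pass both removes ~1/w of white-noise variance and inflates the
sample variance through induced anticorrelation, and the exact factor
accounts for both.  Per-pixel means are preserved exactly; bleaching at
~20% per series changes the recovered B by < 2% after detrending.

Known bias: the per-pixel ratio estimator Var/mean over 50 frames is
biased low by ≈ 0.01 at the default intensities (second-order
delta-method; verified by simulation).  The package reports the estimator
as defined rather than correcting it, since condition comparisons use the
same estimator; recovered condition means land ~0.01 below the generating
B = 1 + ε.

Oligomer classes: a line through the monomer/dimer/trimer reference B
values, extrapolated to the hexamer, seeds a k = 6 K-means over the pixel
B values; each final cluster is ascribed to the class with the nearest
predicted B (many-to-one, so clusters splitting one brightness mode stay
in one class), and percentages per class are averaged across cells.
Degenerate inputs (fewer distinct values than classes) fall back to
nearest-center assignment.

## Time-gated FLIM

Gate i of N (width 2 ns) collects the analytic integral of the decay over
[2(i−1), 2i] ns, Poisson-sampled; multi-exponential decays weight
components by photon fraction within the window; no excitation-pulse
wrap-around is modeled (the 10-gate/20-ns window exceeds a typical 12.5-ns
laser period; real acquisitions would fold late photons into early gates).
The per-pixel estimate is the gate-delay-weighted mean with Δtᵢ = 2i−1 ns
after 3×3 uniform smoothing; pixels below an intensity floor (default 100
counts post-smoothing) are masked.  The gated mean is a *biased* estimator
of the true exponential lifetime (window truncation); it is reported as
defined and never corrected, because conditions are compared with the same
estimator.  It is exactly bounded by the first and last gate delays,
scale-invariant, and strictly increasing in the true decay constant.
Per-cell lifetimes default to the unweighted mean over defined pixels; an
intensity-weighted option exists.  FRET verdicts require a two-tailed
t-test at p ≤ 0.05 *and* a donor-lifetime decrease.

## Pipelines, configuration, reproducibility

Run configuration is one YAML file with per-stage sections; unknown keys
are rejected and every stochastic stage takes an explicit seed (identical
seed ⇒ bit-identical output, including all generators).  Condition
manifests map condition names to input files plus comparison pairs.
Reports carry a hash of the configuration.  Condition-pair p-values are
reported raw (no multiple-testing correction), with Bonferroni left to the
caller, matching common practice for these assays.

## Problem sizes

Tests and the acceptance script use 50-frame 256×64 (or smaller) N&B
series, 8–20 localization ROIs of 4×4 µm at ~1800 localizations/µm², and
16×16–32×32 gated stacks at 10⁴ photons/pixel — sizes chosen to keep
sampling error comfortably inside the stated tolerances while the whole
suite runs in well under a minute of compute per analysis family.

## Known limitations

- The classification operates on fit-error distributions, so its power
  depends on ROI count and density; below ~8 ROIs it refuses to run.
- The tail-to-1 normalization assumes r_max reaches the flat regime; for
  ξ ≳ r_max/5 the normalization itself would bias A and ξ.
- The exponential-pc kernel tabulation assumes the target correlation has
  a non-negative spectrum (true for the exponential family); other targets
  raise a construction error rather than silently mis-sampling.
- Manual quality control of acquisitions (e.g. discarding series with
  gross membrane movement) is outside the package; a variance-outlier
  warning in the logs is the only automation.
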