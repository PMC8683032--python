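# Methods

## Generative model

A run's pupil trace is treated as the sum of three components: spontaneous
fluctuation (SF), event-locked cognitive responses (PR), and one
blink-locked response (BPR) per blink. Analysis operates on 3-s windows
resampled to 16 points at 5 Hz ({0, 0.2, …, 3.0} s, block means of the
native samples); blink-affected windows are anchored at blink offsets,
blink-free windows are carved out of inter-blink intervals longer than 6 s
after discarding the first 3 s (still contaminated by the previous blink)
and chunking the rest into 3-s pieces.

The background (SF + PR) is modelled, after a box-cox power transform `g`
with exponent λ, as multivariate normal with a stationary AR(1) covariance
`σ²ρ^|k−l|` — pupil noise is strongly autocorrelated even at 5 Hz. The
blink response is a shifted, scaled gamma density in shape–scale form,
`h(x) = γ f(x − t; α, β)`, with γ < 0 for the usual constriction and a
per-blink multiplicative gain θ_j. The gamma family captures the
characteristic profile — a delay of a few hundred ms, fast constriction to
a trough (canonically −0.2 mm at ~0.9 s), slow re-dilation, flat by 3 s —
with four interpretable parameters; a monophasic kernel suffices because
rebound tails are negligible in this preparation.

Because band-passed segments are near zero mean and the classic box-cox
transform requires positive data, a two-parameter (shifted) transform is
used: the shift is `max(0, 0.01 − min(values))` over the run's pooled
segment values, computed once per run. With λ near 1 the transform is
close to affine and the model reduces to an additive Gaussian one.

## Preprocessing

Blink candidates are missing samples, readings below 1 mm, and samples
where a zero-phase 3rd-order 10-Hz high-pass exceeds 0.25 mm in absolute
value; candidates closer than 200 ms belong to one blink, whose
onset/offset are the cluster's first/last candidates. Artifact removal
invalidates 150 ms before each onset and a data-driven post-window: the
first time the boxcar-smoothed (0.25 s) absolute derivative of the raw
trace drops below 0.1 mm/s, clamped to 200–500 ms after the offset;
everything invalidated is linearly interpolated. The cleaned trace is
band-passed at 0.02–4 Hz (3rd-order Butterworth, zero-phase). Two
numerical choices here: filtering is zero-phase to preserve blink-locked
timing, and the 0.02-Hz edge is realized as drift subtraction — the same
Butterworth low-pass run on a ~10-Hz block-mean decimated copy and
interpolated back — because a 0.02-Hz IIR high-pass designed directly at a
500-Hz rate has pole radii within 1e-4 of the unit circle and is not
numerically trustworthy. The first and last 5 s of a filtered run are
excluded from segment extraction (edge transients).

## Inference

Staged maximum likelihood per run, mirroring the factorization of the
model:

1. **λ, shift** — profile box-cox likelihood on the pooled blink-free
   values (shift chosen over the whole run so blink troughs stay
   transformable); λ clamped to [−2, 3].
2. **Mean profiles** — `μ_free` is the pointwise mean of transformed
   blink-free segments. `μ_affected` is a natural cubic spline through the
   first two and last two grid points of the transformed blink-affected
   mean: the interior of that mean is the blink response itself, so only
   the uncontaminated ends may constrain the background.
3. **σ, ρ** — joint MLE over the transformed blink-free segments
   (L-BFGS-B; sufficient statistics against the tridiagonal AR(1)
   inverse), initialized at the sample SD and lag-1 autocorrelation.
4. **Kernel (α, β, γ, t)** — maximizes
   `MVN(g(Ȳ_aff − h); μ_affected, Σ/n)` on the mean affected segment.
   The likelihood surface has separated basins in (α, t), so the local
   optimizer is seeded from a deterministic grid over those two with
   (β, γ) solved from the observed trough time and depth, plus seeded
   jittered starts; the best few are refined. The shape stage uses only
   *isolated* blinks (nearest neighbour > 3 s) when at least 10 exist:
   overlapping neighbours leak their responses into the affected mean and
   its end anchors and measurably shrink the fitted amplitude.
5. **θ_j** — one bounded 1-D search per blink on [−2, 10]. Blinks with a
   neighbour within 3 s use a reference profile in which the neighbour's
   footprint is padded out of `μ_affected`, and then get two conditioning
   sweeps: the 1-D search is re-run after subtracting the neighbours'
   current estimated components on the segment grid. Without this,
   neighbours at ~1-s lags bias amplitudes low by ~15% under the AR(1)
   weighting.

Runs with zero blinks return a flagged model with no kernel; below the
10-segment floor the kernel stage falls back to a user-supplied canonical
kernel if provided, otherwise raises. All estimators accumulate sums in a
sorted (canonical) order so results are exactly invariant to segment
ordering.

## Correction

Model-based correction subtracts `θ̂_j ĥ` at the native sampling times
over each blink's `[offset, offset + 3 s]` footprint; overlapping
footprints subtract additively and the correction is exactly invertible.
Inside peri-blink artifact windows the data is an interpolated chord, so
the subtracted component is likewise the chord of the kernel across that
window — subtracting the raw kernel there over-corrects data from which
the early response was already removed. The comparator implements the
common practice: each blink's window, from the pre-artifact start to 3 s
after the offset (merged when overlapping), is replaced by the straight
line between the boundary samples — anchored at the artifact-window edges,
not the contaminated blink samples.

## Simulator

The generator composes traces forward from the model at native rate: an
AR(1) Gaussian process on the 5-Hz grid (σ = 0.05, ρ = 0.8, λ = 1 by
default), inverse-transformed, cubic-upsampled and centred; per-condition
cognitive profiles tiled over trials; blink trains from inhomogeneous
Poisson thinning against per-trial, condition-dependent rate profiles with
a 0.2-s absolute refractory; per-blink gains from a gamma distribution
with mean 1 and CV 0.6 (heavy right spread, matching the several-fold
amplitude range between top and bottom quantiles); and blink gaps stamped
as missing samples so the detection path is exercised end to end. The
default kernel is α = 4, β = 0.2 s, t = 0.3 s with γ solved for a −0.2-mm
trough at 0.9 s — constriction beginning ~0.3 s after the blink offset and
recovery by 3 s. Defaults for the noise were chosen once as a realistic
regime (trough SNR ≈ 4; strong 5-Hz autocorrelation).

Three study configurations ship with the package: `fixation_config`
(constant 0.28-Hz blink rate, no cognitive response — a typical quiet
fixation run), `oddball_config` (2-s trials, stimulus-locked dilation,
blink rate suppressed during the stimulus with a post-stimulus bump; mean
rate ~0.38 Hz), and `load_config` (7.5-s working-memory-style trials with
a retrieval-locked dilation whose amplitude grows with load and blink-rate
bumps in the preparation epoch and at retrieval onset whose height also
grows with load — the confounded design where blink rate counteracts the
effect of interest).

What the simulator does *not* emulate: gaze-position artifacts, luminance
responses, eyelid occlusion geometry, measurement quantization,
slow-drift nonstationarity, and between-subject variability. Passing
tests therefore certify the algorithmic chain under the stated generative
assumptions, not robustness to every property of real recordings.

## Evaluation battery

* **Correction efficacy**: Euclidean distance between the mean blink-locked
  and mean blink-free 16-point profiles, before vs after correction,
  across seeded runs.
* **Confound prediction**: the expected trial time course equals the tiled
  cognitive profile plus the convolution of the blink-offset-rate profile
  (Hz) with the kernel, carried across trial boundaries from a
  steady-state past and re-baselined at each trial onset; validated
  against trial-averaged simulation.
* **Blink-history sequences**: trials grouped by their 4-trial blink
  pattern ([0 0 0 1] = blink in the current trial only, etc.); the
  current-blink group shows late suppression, the previous-blink group
  early inflation, relative to fully blink-free sequences.
* **Discriminability and power**: window-averaged, per-trial-baselined
  response magnitudes (run-wise demeaned for mean/SEM comparisons,
  z-scored for AUC/bootstrap), Mann–Whitney AUC with ties counted ½, and
  a bootstrap power curve: resample n trials with replacement, OLS of
  magnitude on the coded condition, two-sided slope test at α = 0.01,
  10,000 repetitions (1,000 in the cross-method comparison); the reported
  figure is the smallest n reaching a 95% rejection fraction. The type-I
  calibration check uses a pool orthogonalized to carry exactly zero
  slope, isolating the machinery's calibration from the pool's chance
  correlation. No multiple-testing correction is applied inside the power
  analysis (one slope test per resample).
* **Quantile profiles**: per-segment amplitude is the trough within
  0.5–1.2 s after the blink offset; quantile binning within stratum,
  equal-weight averaging across strata, and a GCV-tuned cubic smoothing
  spline before peak readout.

## Problem sizes

The test suite and acceptance script run simulations at sizes chosen to
estimate each quantity with comfortable Monte-Carlo margin on one CPU:
fixation runs of 240 s at 50 Hz (100 seeds) for efficacy; a 4,000-s run
(2,000 trials) for the confound prediction; 1,200-s runs across 20 seeds
for sequence effects; 3,600-s load-design runs (480 trials) for the
comparator and power analyses; and 200–1,000 directly simulated segments
for the parameter-recovery checks.

## Known limitations

* The first two spline anchors of `μ_affected` (0 and 0.2 s post-offset)
  always fall inside the peri-blink artifact window, so they are
  chord-valued by construction; this biases the fitted kernel amplitude
  slightly low (~10% in the bursty-blink regime). It is intrinsic to
  anchoring the background on the window ends of offset-locked segments.
* In designs with strong condition-coupled blink bursts, the corrected
  condition difference recovers ~85–95% of the ground-truth difference;
  the residual traces to the anchor bias above plus remaining
  overlapping-blink amplitude error.
* λ is weakly identified when the data's coefficient of variation is
  small (shifted near-zero-mean segments); this is harmless because the
  transform is then nearly affine, but fitted λ values should not be
  interpreted on their own.
* The method needs enough blinks (≥ 10 affected windows by default) and
  enough blink-free data per run; very high blink rates leave little
  blink-free background to model.
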