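# Methods

This note documents the models behind `memprobe`, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the
numerical decisions a maintainer should know about.

## Single-molecule model

A membrane-bound probe is modeled as a 2D Brownian walker with diffusion
coefficient D (µm²/s) that leaves the membrane after an exponentially
distributed dwell.  Two first-order processes end a dwell and are
indistinguishable frame-by-frame: true dissociation (rate k_off) and
photobleaching, taken proportional to illumination power P (rate β·P).
Rates add for independent exponential hazards, so the observed rate is

    k_obs(P) = k_off + β·P.

This linearity is what licenses the photobleaching correction: ordinary
least squares of per-cell k_obs on P, extrapolated to P = 0, estimates
k_off; its reciprocal is the true membrane lifetime.  The extrapolation
treats each cell's fit as one observation (cells are the unit of
replication); a per-power-mean variant would weight powers equally instead,
and with balanced designs the two coincide in expectation.

Observation model: positions are sampled every Δt = 60 ms (16.7 Hz), the
frame rate of the experiments this package models; reported positions add
i.i.d. Gaussian localization error of σ = 20 nm per axis per frame, a
standard figure for bright single-molecule labels (the source experiments
did not report theirs; this default is a placeholder, not an inference).
Motion blur is ignored (exposure shorter than the frame interval).  A dwell
of length T is observed as n = ⌊T/Δt⌋ + 1 frames, and appearances shorter
than `min_track_frames` (default 2 — a single-frame appearance cannot be
tracked) are discarded.  This discretization has two consequences the
analysis must respect:

1. **Left truncation** — short dwells are censored from below, so lifetime
   fits condition on duration ≥ t_min.
2. **Frame quantization** — observed frame counts are *geometric*, not
   exponential: P(n = m) ∝ e^(−k(m−1)Δt).  At the conditions of interest
   (kΔt ≈ 0.4–1.3 once bleaching is added) this is far from the continuum
   limit.

### Lifetime estimators

`fit_lifetime` offers three methods; durations are (n_frames − 1)·Δt and
`t_min` defaults to the shortest observed duration.

* `grid_mle` (default) — the MLE for geometric frame counts: with
  j = duration/Δt and j_min = t_min/Δt, q̂ = (mean j − j_min)/(mean j − j_min + 1)
  and k̂ = −ln(q̂)/Δt.  This is the left-truncated exponential fit carried
  out *on the frame grid*, and it is exactly consistent under the
  observation model above.  It is the default because the continuous
  estimator below is biased by a factor (e^{kΔt} − 1)/(kΔt) — about +25% at
  kΔt = 0.43 and +110% at kΔt = 1.33 — which the zero-power extrapolation
  then amplifies (the bias is convex in power, so the fitted line
  undershoots at P = 0; in simulation the recovered 140 ms lifetime comes
  out near 340 ms).  With `grid_mle` the same pipeline recovers the truth
  to within sampling noise (a few percent at 10 cells × 300 tracks/power).
* `truncated_mle` — the closed-form continuous-time MLE
  k̂ = 1/(mean duration − t_min).  Appropriate when Δt ≪ 1/k (it agrees
  with `grid_mle` to first order in kΔt); kept both for that regime and as
  the textbook reference estimator.
* `survival_lsq` — OLS of log empirical survival versus duration, the
  curve-fitting analog of a one-phase exponential fit to the lifetime
  distribution.  Tail points with fewer than 5 remaining observations are
  dropped, since log-survival noise diverges in the tail.  On clean
  continuous exponentials at n = 5000 it agrees with `truncated_mle`
  within 5%.

Censored tracks (ended by leaving the field of view) are excluded from
lifetime fits and counted in the result.

### MSD, diffusion, and the deviation ratio

Per cell, the time-averaged MSD uses **all overlapping in-track pairs**
pooled across tracks (pair-weighted), which extracts the most from the many
short tracks an exponential dwell produces; lags with zero pairs are
omitted.  Cell curves are then averaged **unweighted** into a grand curve
with SEM across cells, matching a cells-as-replicates design.

D comes from OLS of MSD(τ) = 4Dτ + c over frame lags 2–4 (configurable).
Lag 1 is excluded because static and dynamic localization errors distort it
most; the free intercept c absorbs the remaining offset 4σ² ≈ 0.0016 µm².
A negative fitted D or intercept is reported with a validity flag, never
clamped.

The deviation ratio rd = MSD(τ_test)/(4D̂τ_test + ĉ) uses test lag 10 by
default.  The underlying idea — compare the measured long-lag MSD to the
short-lag Brownian extrapolation — admits several published variants; the
ratio form used here is self-normalizing (scale-invariant when c = 0) and
maps Brownian → 1, confined → <1, directed → >1.  A reflecting-box
simulation mode exists solely to exercise the confined branch.

The dwell displacement r = √(2D/k_off) is the RMS 1D excursion over one
mean dwell; with D = 0.3 µm²/s and 1/k_off = 140 ms it evaluates to
≈ 290 nm.

## Image quantification

* **Normalized subtraction** — each channel is divided by its own ROI mean
  (after camera-offset subtraction), then reference is subtracted from
  biosensor.  The ROI mean of the result is identically 0, which doubles as
  a numerical self-check; all outputs are invariant to positive rescaling
  of either channel.  The headline scalar is the mean of the subtracted
  image over a peripheral **rim band** — the ROI minus its erosion by
  `rim_width` px (default 5, 3×3 structuring element) — because peripheral
  enrichment is exactly what a membrane-bound biosensor should show.  The
  full subtracted image is always returned alongside.
* **Compartment masks** — Otsu's threshold (between-class variance
  maximizer) on the in-ROI marker histogram, foreground = pixels strictly
  above the threshold, components smaller than `min_size` px removed.  For
  integer-valued data the threshold is computed on the exact per-value
  histogram rather than a 256-bin approximation, so tied values classify
  consistently.  Masks are recomputed per frame by default (compartments
  move); empty-mask frames propagate as missing values, never zeros.
* **Masked traces** — per frame, mean reporter intensity inside the mask is
  divided by the mean over the whole ROI, canceling expression level and
  photobleaching, then baseline-normalized as F_t/F_pre.  The min–max and
  ΔF/|ΔF|_max variants are applied per cell (not to averaged traces).
  AUC is a trapezoidal integral of (normalized − baseline) with linearly
  interpolated window endpoints.

## Synthetic data: what it does and does not emulate

The trajectory simulator reproduces the *statistical* structure the
analyses assume — exponential dwells with additive bleach rate, Gaussian
steps, frame quantization, localization noise, uniform initial placement in
a 16 µm field — and is exact by construction, which is what makes the
parameter-recovery tests meaningful.  It does **not** render
diffraction-limited movies, simulate detection/linking, or model motion
blur, non-uniform illumination, or state switching; passing tests therefore
validate the analysis chain given correct tracking, not the tracking
itself.  Boundary exits are ignored by default (`unbounded`): at
D ≈ 0.3 µm²/s and dwells ≲ 200 ms, RMS excursions are ≪ the 16 µm field, and
keeping dwells boundary-free keeps the lifetime oracle exact; a
`censor_at_fov` mode exists and censored tracks are flagged.

Image phantoms are piecewise-constant geometries (uniform cytosol, uniform
rim or disk-shaped puncta) with optional Poisson or Gaussian noise; they
test normalization and masking arithmetic exactly, but contain no PSF,
shading, or cell morphology.  Every generator is bit-reproducible: one
master seed spawns independent substreams per cell/channel/frame.

## Defaults of record

| parameter | default | note |
|---|---|---|
| diffusion_coeff | 0.3 µm²/s | membrane-probe scale this package targets |
| k_off_true | 1/0.140 s⁻¹ | 140 ms mean dwell |
| frame_interval | 0.060 s | 16.7 Hz imaging |
| localization_sigma | 0.020 µm | placeholder, per-axis |
| fov_size | 16 µm | square field |
| min_track_frames | 2 | shortest trackable event |
| fit lags / test lag | 2–4 / 10 | short-lag fit, long-lag deviation test |
| rim_width | 5 px | peripheral band for subtraction summary |
| Otsu min_size | 4 px | speckle removal |

Problem sizes used by the test suite and the acceptance script — 10–12
cells × 200–300 tracks per condition and ≤ 10 simulation replicates — were
chosen so that the estimators' sampling error sits comfortably inside the
recovery tolerances (≈3% SE on the extrapolated lifetime, ≈1% SEM on rd)
while a full run stays in the tens of seconds.

## Known limitations

* The deviation-ratio definition and its test lag are one defensible choice
  among several in the literature; comparisons across packages should fix
  both.
* `grid_mle` assumes dwells start at a frame boundary; sub-frame phase is
  not modeled (its effect is bounded by half a frame on the mean).
* The survival regression is unweighted; a weighted fit would be more
  efficient but adds a variance model the data rarely justify.
* Polygon ROIs are rasterized by pixel-center inclusion; very thin polygons
  can rasterize empty, which is raised as an error rather than silently
  padded.
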