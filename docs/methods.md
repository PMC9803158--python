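# Methods

## Problem

Remote photoplethysmography (rPPG) recovers the blood-volume pulse from the
minute periodic color change of facial skin in ordinary video. The cardiac
modulation of the spatially averaged green channel is well below one 8-bit
intensity unit, while illumination drift and facial motion move the same
average by whole units to tens of units. The pipeline implemented here
denoises a single-channel facial trace and reads out heart rate (HR) per
analysis window, using singular spectrum analysis (SSA) whose components are
pruned globally by a robust-PCA low-rank/sparse split and locally by an
autocorrelation periodicity score.

## Processing chain

For a trace x(n), n = 1..N at fps Hz (nominally 30):

1. **Skin masking and averaging** (when starting from frames): a pixel is
   skin iff R > 95, G > 40, B > 20, max(R,G,B) − min(R,G,B) > 15, R > G,
   R > B and hue H ∈ [0°, 60°] (HSV hexcone hue; hue is identical in HSV and
   HSL so the choice is immaterial). Intensity comparisons are strict as
   printed; the hue bound is inclusive. The per-frame mean of the chosen
   channel over mask-true pixels forms the trace; a frame with an empty mask
   reuses the previous frame's value.
2. **Detrending** by smoothness priors: trend = (I + λ²D₂ᵀD₂)⁻¹x with D₂
   the second-difference operator; the detrended signal is x − trend.
   Default λ = 300, which at 30 fps puts the equivalent high-pass cut-off
   near 0.36 Hz — below the 0.7 Hz floor of the HR band, so no cardiac
   energy is removed. λ is dimensionless and should be rescaled if fps
   differs substantially from 30.
3. **Normalization** to zero mean, unit variance, then a **five-point
   moving average** (edges use shrinking symmetric windows so length is
   preserved).
4. **EEMD coarse denoising**: ensemble empirical mode decomposition with
   additive white noise of standard deviation 0.05 × std(input) and 100
   ensemble trials. Sifting uses cubic-spline envelopes through local
   extrema, mirrored two extrema deep past each boundary, Huang's pointwise
   standard-deviation stop criterion with threshold 0.2, at most 10 sift
   iterations per mode and at most 10 modes. (The sifting stop rule and mode
   cap are conventional choices; nothing upstream fixes them.) The intrinsic
   mode function whose zero-padded magnitude spectrum peaks highest inside
   0.7–3 Hz is kept; ties break to the earlier (higher-frequency) mode. On a
   two-tone test signal the 1.2 Hz tone concentrates in the second mode,
   matching the behavior expected of this chain.
5. **SSA**: the window signal (30 s) is embedded as the L × K Hankel
   trajectory matrix with L = round(3 s × fps) — 3 s is a quarter of the
   longest cardiovascular fluctuation period (≈ 12 s) — and decomposed by
   SVD into rank-one components λᵢuᵢvᵢᵀ.
6. **Global pruning**: the trajectory matrix is split into a low-rank part A
   and sparse part E by the exact augmented Lagrange multiplier (EALM)
   iteration for min ‖A‖★ + η‖E‖₁ s.t. X = A + E. The number of retained
   SSA components is s = rank(A) (numerical rank at λ₁·max(m,n)·ε·10,
   clamped to the number of nonzero singular values).
7. **Local screening**: each retained component is mapped back to a series
   by anti-diagonal averaging (computed for rank-one matrices as the
   convolution of the two singular vectors divided by anti-diagonal counts),
   scored by ρᵢ — the largest interior peak of its biased normalized sample
   autocorrelation up to 12 s of lag (lag-0 counts as the first peak, so all
   interior strict local maxima qualify; minimum peak separation 0.25 s) —
   and kept iff ρᵢ > 0.85. If nothing passes, the best-scoring component is
   kept so the window still produces output, and the window is flagged.
8. **Reconstruction**: x_rc = Σ wᵢzᵢ over selected components with
   wᵢ = λᵢ/Σλⱼ normalized over the selected set (the alternative,
   normalizing over all retained components, is available by configuration;
   normalizing over the selected set keeps the output amplitude stable when
   few components survive).
9. **HR readout**: 60 × the argmax frequency of the magnitude spectrum in
   0.7–3 Hz, zero-padded 8× beyond the next power of two (≈ 0.22 bpm grid at
   30 s and 30 fps). Windows are 30 s advanced in 1 s steps; agreement with a
   reference is summarized by MAE, RMSE, Pearson r, and Bland–Altman mean
   difference with ±1.96 σ limits (σ with one delta degree of freedom).

EEMD runs once on the whole trace by default and the SSA stages run per
window; pipelines of this family conventionally decompose the whole facial
signal once before windowed readout, and per-window EEMD multiplies cost
~30× at 1 s steps without changing results appreciably. A per-window mode
remains available (`eemd_scope="window"`).

## EALM details and the sparsity weight

The ℓ₀ sparsity count in the split's objective is relaxed to ℓ₁, which is
what the soft-thresholding update actually minimizes — the standard convex
robust-PCA surrogate. The alternation is: A ← D_{1/μ}(X − E + Y/μ) (singular
value soft threshold), E ← T_{η/μ}(X − A + Y/μ) (entrywise soft threshold),
iterated at most 5 times or until the relative change drops below 1e−6;
then Y ← Y + μ(X − A − E), μ ← 1.5 μ, until ‖X − A − E‖_F/‖X‖_F ≤ 1e−7.
Y₀ = sgn(X)/max(‖sgn X‖₂, η⁻¹‖sgn X‖∞) and μ₀ = 1.25/‖X‖₂. Five inner
alternations per multiplier step were measured to give results identical to
twenty (same recovered rank, same recovery error to 7 digits) on both
rank-recovery oracles and pipeline trajectory matrices, at a third of the
cost; the cap is configurable. Thin SVDs go through the small Gram matrix
eigendecomposition when the matrix is elongated (trajectory matrices are
90 × 811 at default settings), which is several times faster than
divide-and-conquer SVD and accurate far above every threshold used.

The default sparsity weight is η = 1/√max(m,n). The variant η = 1/max(m,n)
is selectable, but it underweights sparsity so strongly on elongated
matrices that the objective favors the degenerate split A = 0, E = X
(λ‖X‖₁ < ‖X‖★ already for typical trajectory matrices), collapsing the
retained-component count; 1/√max(m,n) is the scaling under which the
low-rank/sparse split is identifiable in the robust-PCA literature.

On matrices that are genuinely low-rank plus sparse (rank 5 of 100 × 120
with 5% corruption), the iteration recovers the rank exactly and the
low-rank factor to ~1e−7 relative error. On trajectory matrices of noisy
physiological signals, dense in-band noise is not sparse, so A retains a
large numerical rank (s ≈ 50 of 90 is typical); the global pruning step then
removes only the weakest tail and the autocorrelation screening does most of
the selection work. Windows where EALM fails to converge fall back to the
component count holding 90% of squared singular-value energy and are
flagged.

## Synthetic data

The generator produces what a webcam delivers in this setting: a
quasi-periodic pulse — fundamental sinusoid at the instantaneous HR
(phase-integrated, so piecewise-linear HR schedules give chirps whose
windowed spectral peak tracks the schedule) plus 2 harmonics at relative
amplitudes 0.5 and 0.25 emulating PPG beat asymmetry — riding on a slow
illumination drift sinusoid (amplitude 3 × pulse, period 25 s), sparse
motion transients (random-sign Hann bumps, default 5 frames wide, amplitude
10 × pulse, Poisson event times), and additive white Gaussian noise. All
amplitudes are in units of the pulse fundamental. Everything is a pure
function of the seed.

The artifact amplitude default deserves explanation. Real motion artifacts
in a skin-averaged trace are one to two orders of magnitude above the
cardiac modulation. At ~10 × pulse the artifacts dominate the raw trace
while the pulse pair remains the strongest structure in the 30 s singular
spectrum — the regime this method targets, where its published baselines
err by several bpm. Substantially larger transients expose a structural
limitation measured here and logged in the benchmark analysis: two
transients landing within one embedding window of each other produce an
oscillatory "ring" component (period = their spacing) whose autocorrelation
first peak reaches ~0.94, which the periodicity screening counts as
HR-like; at ~30 × pulse such rings out-weigh the pulse pair and the
screening selects them. This is the same failure the method's authors
acknowledge for periodic motion noise.

What the generator does not emulate: non-stationary illumination spectra,
skin-tone-dependent pulse amplitude, camera quantization and compression,
sustained quasi-periodic motion (the documented failure mode of
autocorrelation screening), or face-tracking jitter. Passing tests on this
generator therefore show correct mechanics and parameter recovery under
stationary noise plus sparse transients, not performance on real video.

Because the band-limited FFT argmax readout is itself highly robust to
transients (a 30 s window integrates the pulse coherently while transient
energy spreads over the band), the raw filtered readout is near-exact under
these conditions, and the three readouts (raw, EEMD-selected, full chain)
agree to ~0.1–0.2 bpm MAE against the generator's schedule. A strict
monotone improvement from raw to EEMD to the full chain does not emerge on
this generator family at any artifact amplitude: the stages begin to differ
only in regimes where ring components already defeat the screening. The
benchmark (`lassa.benchmark`) runs 120 s traces at 30 fps with a 70→80 bpm
schedule over 20 seeds and reports all three MAEs per seed.

## Numerical choices

- FFT magnitude (not power) spectra everywhere an argmax is taken; the
  choice cannot change an argmax and is fixed only for reproducibility.
- IMF spectra are zero-padded to the next power of two ≥ 8N; readout
  spectra to 8 × the next power of two ≥ N.
- Autocorrelation is normalized by its own lag-0 sum, so P(0) = 1 holds
  bitwise for any non-constant series.
- Anti-diagonal means are computed as first-element-plus-mean-deviation, so
  hankelization inverts the trajectory embedding bitwise.
- Autocorrelation peaks are strict local maxima; plateaus take their left
  edge; components with (numerically) zero variance score the −1 sentinel.
- Singular-vector sign indeterminacy never reaches the output: component
  matrices and series use the product of both vectors.
- Seeds: the pipeline consumes a single seed, split via NumPy's
  SeedSequence into the whole-trace EEMD stream and per-window streams.

## Limitations

- Rank-based global pruning is largely inert under dense in-band noise (see
  above); the method's selectivity then rests on the 0.85 autocorrelation
  threshold.
- Sustained or repeated periodic interference (rhythmic motion, flicker) is
  scored periodic and retained; this is inherent to the screening criterion.
- The EEMD dyadic filter bank concentrates band noise into the same mode as
  the pulse; mode-splitting of the pulse across adjacent modes degrades
  single-mode selection when SNR is very low.
- Face detection/tracking is out of scope: the pipeline starts from frames
  plus bounding boxes or from an extracted trace.
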