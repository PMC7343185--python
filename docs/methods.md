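# Methods

## Forward model

A voxel's noise-free BOLD signal is generated in three linear stages: the
frame-wise inner product of the binary stimulus aperture with the sampled
receptive field gives a neural response time series; causal convolution
with a unit-sum HRF kernel (zero stimulus history before frame 0, output
truncated to the stimulus length) gives the hemodynamic response; the
response is scaled so a unit-gain pRF produces a configured peak modulation
(default 10% signal change, the middle of the 8–12% band used to select
calibration voxels) around a zero baseline, and scales linearly with the
pRF gain. Noise is added last. The reference fitter inverts *the same
implementation* — synthesizer and fitter predictions agree to 1e-10 for
identical parameters — so recovery error measures the estimator, never a
forward-model discrepancy.

Fixing the peak modulation rather than the neural gain makes signals
comparable across pRF sizes and stimulus designs; the absolute response
amplitude is carried separately by `response_contrast`, the rms of the
*unscaled* convolved response, which is the quantity that drops when bar
positions are randomized (see Mitigations).

## Stimulus

The visual field is sampled on an odd-sized square grid (default 101 × 101
over 20 deg) so the central sample is exactly (0, 0) deg; x increases with
column index, y decreases with row index. The default protocol is eight
bar sweeps (2 deg bar) along four axes in both directions — horizontal,
vertical and the two diagonals — at 18 s per sweep with a 14 s blank after
every second sweep: 8·18 + 4·14 = 200 frames at 1 s. Slower protocols
(28, 38 s per sweep) keep the frame rate and scale the blanks
proportionally, roughly doubling the samples between the fastest and
slowest variants. Sweep centers are antisymmetrized so opposite sweep
directions are exact time-reverses. The exact direction order and blank
placement are configuration, not a claim of compatibility with any
particular published protocol.

Randomized designs permute the temporal order of the *same* frames (blanks
included) under a seed, so sweep and randomized runs are signal-matched:
identical frame multisets, different temporal structure only.

## HRF kernels

Two parametric families: the canonical two-gamma difference
(shape/rate a₁ = 6, β₁ = 1 for the peak; a₂ = 16, β₂ = 1, relative scale
c = 1/6 for the undershoot; c = 0 gives a literal single gamma) and the
all-positive delayed Boynton gamma (n = 3, τ = 1.08 s, delay = 2.05 s).
Kernels are sampled at the frame interval over 40 s and normalized to unit
sum, so convolution preserves the signal mean and HRF mismatch perturbs
response *shape* only — overall gain is a free fit parameter anyway.

Width manipulation is exact time dilation, h(t/w), which scales FWHM and
time-to-peak together. The default mismatch family dilates the Boynton
kernel by (0.85, 1.0, 1.15, 1.3). Moderate factors matter: dilation also
moves the response peak, and a peak lag of more than ~1 s between
synthesis and analysis kernels inflates the estimated pRF size regardless
of the sign of the width mismatch (the model has no latency parameter to
absorb it). Within this family the size bias is cleanly monotone in width
and changes sign at the matched kernel; far outside it, the lag effect
dominates and the monotone pattern breaks.

## Noise

Additive components: zero-mean Gaussian white noise (SD in percent-signal
units) plus sinusoids for cardiac (1.2 Hz), respiratory (0.3 Hz) and
low-frequency drift (0.01 Hz). Each sinusoid re-draws its frequency and
amplitude per realization (multiplicative uniform(−1, 1) jitter, fractions
0.1–0.3) and a uniform phase, emulating run-to-run physiological
variability; sampling at a 1 s frame interval aliases the cardiac
component, as in real acquisitions. Generation is a pure function of
(spec, length, dt, seed).

The low/mid/high presets were calibrated once against the rms of the
default noise-free bar-sweep signal with a 50/15/15/20% variance split
across white/cardiac/respiratory/drift, targeting single-acquisition SNRs
(20·log₁₀ of the rms ratio) of about +5.3, −0.5 and −4.3 dB — the span
seen in occipital on/off measurements from low- to high-noise gray-matter
voxels. Realized medians land within ~0.3 dB of the targets (the drift
sinusoid does not complete a cycle in 200 s, slightly lowering its
realized rms).

What the generator does not emulate: spatial noise correlation between
voxels, multiplicative (arousal-like) noise, and input-referred noise such
as eye movements. Passing tests therefore certify estimator behavior under
independent, additive, stationary noise — not under every failure mode of
real data.

## Estimation

The reference fitter estimates the circular Gaussian linear model with an
assumed HRF. Stage one is an exhaustive lattice search (x, y over
[−10, 10] deg step 1; σ ∈ {0.5, 1, 2, 4, 8} deg) with gain and baseline
solved per node in closed form; all node regressors are precomputed in one
BLAS pass and cached per (stimulus, kernel, lattice). Ties break toward
smaller σ, then smaller eccentricity. Stage two refines (x₀, y₀, σ) by
bounded L-BFGS-B (bounds x, y ∈ [−20, 20], σ ∈ [0.1, 10], ftol 1e-6) with
the nested linear solve, from the winning node plus two seed-perturbed
starts; the result is never worse than its start, and an optimizer abort
at a numerically zero residual still counts as converged. Negative-gain
solutions are flagged degenerate, as are (near-)constant input series.
`aggregate_median` repeats the fit k times with different multi-start
seeds and takes the component-wise median, the recommended guard against
occasional non-optimal local minima.

## Calibration procedure

Noise levels are estimated from on/off block-design scans: (1) keep voxels
whose mean signal is ≥ 75% of the grand mean (an all-zero scan short-
circuits to an empty survivor set); (2) keep voxels within 80% of the
maximum spectral coherence — amplitude at the stimulus-frequency bin over
the mean amplitude in a ±10-bin window excluding it; (3) convert to
percent signal change and keep modulation amplitudes in 8–12%, where
amplitude is half the peak-to-peak of the PSC series (a ±10% modulation
reads as 10%; the alternative reading, the midpoint of max and min, is
degenerate at ≈0 for any zero-mean PSC series and was rejected). Noise is
the residual of a cycle-locked sinusoid least-squares fit, and SNR is
20·log₁₀(rms(fit)/rms(residual)). Representative voxels at chosen
quantiles of the survivor noise distribution are exposed as a configurable
picker rather than hard-coded percentages.

## Reporting

Error tables join truth to estimates on voxel id (strict one-to-one;
missing or duplicated keys are listed, never dropped silently). Polar-angle
errors are wrapped to (−π, π]; eccentricity error is signed. Summaries trim
to the central ceil(0.9·n) rows ranked by estimated size — outlier fits
manifest as extreme sizes — and report medians, size quantiles and a
covariance-based center ellipse scaled by the χ²(2) quantile at 90% mass
(coverage 0.885–0.915 on large normal samples). The HRF-mismatch matrix is
the median signed size error per (synthesis HRF, analysis HRF) cell of a
complete factorial. All report computations are pure functions of the two
tables; TSV/JSON outputs are bit-reproducible.

## Reproducibility and problem sizes

Every random draw descends from explicit seeds; batch synthesis derives a
per-voxel seed from the master seed and the voxel counter via
`SeedSequence([master, index])`, so any single voxel is reproducible in
isolation. The bundled validation experiments use 25 repetitions per noise
level and the 4 × 4 HRF family — enough for stable medians and the
spread-ordering comparisons; the full-scale experiment (100 repetitions)
is a configuration change, not a code change.

## Known limitations

- Only the circular Gaussian is *fitted*; elliptical and DoG fields (and
  the DoG's independent surround, read as the intended generalization of a
  notationally shorthand center/surround form) are synthesis-only.
- No compressive (CSS) exponent and no HRF-parameter fitting.
- The voxel dimension is an indexed list (one-dimensional NIfTI), not a
  volumetric geometry; anatomical masking is the caller's job.
- The calibration amplitude filter inherits the noise sensitivity of
  peak-to-peak measures; heavy noise inflates the measured modulation.
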