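# Methods

This note documents the models, conventions, parameters and design
decisions behind `crowtag`, and what its synthetic-data tests do and do
not demonstrate about field data.

## Conventions

Time is seconds from file start; intervals are half-open `[start, stop)`,
so duration = stop − start and boxes that touch at an endpoint do not
intersect (their IoU is 0). Audio samples are floats on a full scale of
[−1, 1]; integer WAV data is scaled by 1/2^(bits−1). dBFS is referenced to
a full-scale *constant* signal: level = 20·log₁₀(RMS), so a full-scale
sine measures −3.01 dBFS. (The alternative sine-referenced convention
would shift every level by +3.01 dB; the constant-referenced one is used
consistently everywhere, so SNRs — level differences — are unaffected by
the choice.)

## Detection evaluation

**Matching.** Predicted and annotated boxes are matched one-to-one,
class-agnostically, per audio file. Admissible pairs must have interval
IoU strictly greater than the threshold (default 0.5). Among admissible
pairings the matcher maximizes (1) the number of pairs and (2) the total
IoU, in that lexicographic order. This is solved exactly by a linear
assignment on edge weights `iou + B`, where `B` exceeds any achievable
total IoU, so pair count strictly dominates. Selection tables sort their
rows canonically at construction, which makes the result independent of
input row order; remaining ties between equal-total-IoU optima are broken
deterministically by the assignment solver on the canonical ordering.

**Scoring.** Labels are compared after matching. A matched pair with equal
labels is a TP for that class; with different labels it is an FN for the
annotated class plus an FP for the predicted class (detection succeeded,
classification failed). Unmatched annotations are FNs; unmatched
predictions are FPs. The *Unknown* label is neutral throughout: missed
Unknown annotations cost nothing, matched pairs involving an Unknown
annotation contribute nothing, and Unknown-labelled predictions (maximum
class probability ≤ 0.5) never enter the four-class scores. A class-blind
detection-level P/R is available separately (`detection_counts`). Metrics
with zero denominators are 0 by convention and flagged. Macro metrics are
unweighted means over the four scored classes.

## Call level and SNR

A call's level is the RMS of the waveform over its span, in dBFS. Its SNR
is 20·log₁₀(signal RMS / noise RMS), where the noise RMS is measured over
the nearest contiguous 4-s window that contains no focal vocalization.
Non-focal and chick calls may fall inside the noise window — from the
tag's perspective they are part of the acoustic background. Candidate
windows slide outward from the call in 0.1-s steps on both sides; the
feasible window with the smallest gap wins, ties broken toward earlier
time (so at gap 0 the window ending at the call's start beats the one
starting at its stop). The window may abut the call's own span. If no
feasible window exists in the file the call is skipped and logged.

Calls with SNR strictly above 60 dB are flagged and excluded as clipping
artifacts (exactly 60 dB is kept). Confidence filtering keeps detections
with detection probability strictly above 0.5 *and* target-class
probability strictly above 0.5. Chick-call subsampling draws exactly 100
calls (configurable) without replacement, under a seed, from every
(individual, day) group with at least that many detections; by default
the file identifier stands in for the recording day. No denoising is
applied at any point.

Distribution summaries use linearly interpolated quartiles with 1.5-IQR
whisker bounds; amplitude densities are Gaussian KDEs on a shared dBFS
grid, each renormalized to unit trapezoidal integral so differently sized
groups are comparable.

## Acceleration processing

**Normalization.** All three axes are scaled by 1/mean(‖a‖) so the mean
magnitude of the acceleration vector equals 1 (in lieu of per-tag
offset/gain calibration, which requires tag-internal tooling; the
synthetic generator produces pre-calibrated traces). Dive clips are
re-normalized per clip before decomposition, so the 1.8-g peak threshold
operates in per-clip normalized units.

**Decimation.** 200 → 50 Hz by a factor of 4: a zero-phase FIR low-pass
with cutoff at 0.8× the target Nyquist, then every 4th sample.

**Static/dynamic split.** The dynamic component is a delay-free high-pass
at 3 Hz: a linear-phase symmetric FIR built as the spectral complement of
a unity-DC-gain Hamming-window low-pass (67 taps at 50 Hz ≈ 4·fs/cutoff,
odd), applied on reflect-padded data with the (taps−1)/2 group delay
removed. Building the high-pass as `x − LP(x)` guarantees exactly zero DC
response, so a constant trace is entirely static and the additive
identity static + dynamic = raw holds to machine precision. Output length
equals input length.

**Clips and segments.** 2-minute clips are centered on annotated dive
timepoints, clamped to the trace, and merged when they overlap.
Segmentation separators are maximal runs of at least 5 s in which the
*dynamic* vector magnitude stays below 0.2 g — gravity keeps the raw
magnitude near 1 g, so the threshold is only meaningful on the dynamic
component. Active spans are kept iff strictly longer than 20 s. Non-dive
flight segments are supplied as labelled intervals; in the field they are
identified manually from audio cues (flight sounds after nest visits).

**Peaks and the test.** Static-z peaks are local maxima of height ≥ 1.8
(normalized g) with a minimum separation of 50 samples (1 s at 50 Hz);
among closer maxima the higher (then earlier) one survives — the standard
`find_peaks(height=1.8, distance=50)` parameterization. Peaks are
detected on the z-channel only; the y-channel also shows banking
excursions but is not tested. Each segment's `has_peak` feeds a 2×2 table
(category × peak presence) evaluated with an exact two-sided Fisher test:
with margins fixed, the first cell is hypergeometric, and the p-value
sums the probabilities of all tables no more probable than the observed
one (1e-12 relative slack for floating-point ties), accumulated in log
space via `gammaln`/`logsumexp`. For the dive/flight table 11, 9 / 3, 17
this yields p = 0.018701.

**Spectrogram.** For visual inspection of wingbeat structure: Hann
window, 128-point frames and FFT, hop 12, centered frames with zero
padding — frequency rows 0…fs/2.

## Synthetic data: what it emulates, and what it does not

**Soundscapes.** Calls are Tukey-windowed (α = 0.25) sums of three
harmonics of a template fundamental (1.2/1.8/2.3 kHz for adult, chick and
cuckoo templates — placed above the 500-Hz front-end corner), scaled so
the RMS over the call span equals `peak_dbfs` − 3.01 dB (the
sine-equivalent level). The background is white Gaussian noise at a
specified dBFS; the tag front end is a first-order Butterworth high-pass
applied last. The constructed SNR of a call is therefore
(peak_dbfs − 3.01) − noise_dbfs, and recovery tests use a ±2 dB band:
at low constructed SNRs the call-span RMS necessarily includes the noise
power, which inflates the estimate by up to ≈ 1.5 dB at a true 4-dB SNR —
a property of the SNR definition itself, not an implementation error.
Default scenario levels span the −73 to −2.5 dBFS range observed on real
tags; a reduced 8-kHz sample rate is the test default (the native
46.875 kHz is supported) to keep suites fast.

**Detection scenarios.** Annotations are laid out without overlap
(1–3-s gaps), with lognormal durations of median 0.33 s — the observed
median call duration. Predictions are derived by per-event deletion
(miss rate), boundary jitter (± a fraction of the duration), label flips,
and spurious insertions. The expected per-class confusion is computed by
an *in-module exhaustive matcher* (connected components of the admissible
IoU graph, full enumeration within each) — a code path deliberately
disjoint from the evaluator's assignment solver, so closure tests are a
genuine dual route.

**Acceleration traces.** Gravity along a configurable axis plus a
z-dominant wingbeat sinusoid (default 5 Hz — a free generator parameter,
not a species estimate), sub-3-Hz Gaussian banking bumps (the width
parameter is the FWHM) that raise static z to each dive's peak value,
0.1-s landing impulses, and white sensor noise (σ = 0.02 g per axis,
keeping quiet gaps far below the 0.2-g threshold). Quiet gaps gate the
wingbeat off.

**Limits of what passing tests show.** The generators produce idealized
morphologies: calls are stationary harmonic stacks (no real crow spectro-
temporal structure, no reverberation, no overlapping background biophony);
flight is a fixed-frequency sinusoid (no gait changes, gliding, or wind
gusts); banking is a clean Gaussian bump. Tests therefore demonstrate
that the *operations* are correct and mutually consistent at their stated
tolerances — not that the thresholds (0.5 IoU, 0.2 g, 1.8 g, 60 dB)
generalize to any particular field deployment. The trained neural call
detector of the original study is out of scope; a short-window RMS energy
detector stands in purely as pipeline plumbing.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to exercise every
code path with comfortable margins: 1,000 random matching instances with
≤ 8 boxes per side against brute force; 100 detection-scenario seeds
(80 events each) for exact confusion closure; 100 8-s soundscapes at
8 kHz for SNR recovery; 50 acceleration cohorts (600 s at 50 Hz, one dive
clip and two flights each) for ≥ 95% category recovery; 500 random 2×2
tables with margins ≤ 12 against rational-arithmetic Fisher enumeration.
Zero-denominator metrics are defined as 0 and flagged; the noise-window
search uses a 1-ns feasibility tolerance so windows may exactly abut
calls and file edges despite floating-point stepping; WAV round-trips are
exact to 16-bit quantization (RMS within 1e-4).
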