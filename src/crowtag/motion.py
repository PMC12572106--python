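"""Tri-axial acceleration processing and dive discrimination.

The accelerometer signal mixes gravity/posture (static, low frequency) with
movement (dynamic, high frequency).  The two are separated with a
delay-free high-pass: a linear-phase symmetric FIR (Hamming window, 3-Hz
cutoff) applied on reflect-padded data with the group delay removed, so
``static + dynamic == raw`` sample-exactly.  Anti-predatory dives produce
slow, high-amplitude banking excursions in the static z-channel; ordinary
flight does not.  The pipeline extracts 2-minute clips around annotated
dive timepoints, splits clips into flight segments separated by quiet
spans (>= 5 s of dynamic vector magnitude < 0.2 g), keeps segments longer
than 20 s, detects static-z peaks (height 1.8 g, minimum 1-s separation at
50 Hz), and compares the proportion of dive vs non-dive segments that
contain at least one peak with an exact two-sided Fisher test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.special import gammaln, logsumexp

from .formats_io import AccelTable


@dataclass(frozen=True)
class MotionConfig:
    decim_factor: int = 4
    hp_cutoff_hz: float = 3.0
    fir_taps: int = 67
    peak_height_g: float = 1.8
    peak_min_sep_samples: int = 50
    clip_half_width_s: float = 60.0
    quiet_span_s: float = 5.0
    quiet_mag_g: float = 0.2
    min_segment_s: float = 20.0
    spec_nfft: int = 128
    spec_hop: int = 12
    spec_win: int = 128

    def __post_init__(self) -> None:
        if self.fir_taps % 2 == 0:
            raise ValueError("fir_taps must be odd (symmetric linear phase)")
        if self.peak_min_sep_samples < 1:
            raise ValueError("peak_min_sep_samples must be >= 1")
        for name in ("decim_factor", "hp_cutoff_hz", "clip_half_width_s",
                     "quiet_span_s", "quiet_mag_g", "min_segment_s",
                     "spec_nfft", "spec_hop", "spec_win"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Segment:
    """One flight segment with its peak evidence."""

    start_s: float
    stop_s: float
    category: str  # "dive" or "non_dive"
    peak_times_s: list[float] = field(default_factory=list)

    @property
    def has_peak(self) -> bool:
        return len(self.peak_times_s) > 0


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of segments by category (rows: dive, non-dive) and peak
    presence (columns: has-peak, no-peak)."""

    a: int  # dive, has peak
    b: int  # dive, no peak
    c: int  # non-dive, has peak
    d: int  # non-dive, no peak

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def normalize_accel(t: AccelTable) -> AccelTable:
    """Scale all three axes so the mean acceleration-vector magnitude is 1."""
    mean_mag = float(np.mean(t.magnitude()))
    if mean_mag == 0.0:
        raise ValueError("all-zero trace cannot be normalized")
    return t.replace_xyz(t.xyz / mean_mag)


def decimate_accel(t: AccelTable, factor: int = 4) -> AccelTable:
    """Anti-alias low-pass (cutoff 0.8x the target Nyquist, zero phase) then
    keep every ``factor``-th sample."""
    if factor < 1:
        raise ValueError("decimation factor must be >= 1")
    if factor == 1:
        return t
    target_fs = t.fs / factor
    cutoff = 0.8 * (target_fs / 2.0)
    taps = 4 * factor * 8 + 1  # generous length for > 20 dB stopband
    h = signal.firwin(taps, cutoff, fs=t.fs)
    xyz = np.column_stack(
        [_zero_phase_fir(t.xyz[:, k], h) for k in range(3)]
    )
    xyz = xyz[::factor]
    n = len(xyz)
    return AccelTable(t.t[0] + np.arange(n) / target_fs,
                      xyz[:, 0], xyz[:, 1], xyz[:, 2], target_fs)


def _zero_phase_fir(x: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Apply a symmetric odd-length FIR with reflect padding and the group
    delay removed: output aligned with input, same length."""
    half = (len(h) - 1) // 2
    if len(x) <= half:
        raise ValueError(f"trace of {len(x)} samples too short for {len(h)} taps")
    padded = np.concatenate([x[half:0:-1], x, x[-2:-half - 2:-1]])
    return np.convolve(padded, h, mode="valid")


def decompose_static_dynamic(
    t: AccelTable, cfg: MotionConfig = MotionConfig()
) -> tuple[AccelTable, AccelTable]:
    """Split into static (gravity/posture) and dynamic (movement) parts.

    The dynamic part is the delay-free high-pass output (linear-phase
    symmetric FIR, Hamming window, ``hp_cutoff_hz`` cutoff, group delay
    corrected); the static part is ``raw - dynamic`` exactly, so the two
    always sum back to the input.
    """
    if len(t) <= cfg.fir_taps:
        raise ValueError(
            f"trace of {len(t)} samples too short for {cfg.fir_taps}-tap filter"
        )
    # high-pass as the spectral complement of a unity-DC-gain low-pass:
    # guarantees zero response at DC, so a constant trace is all static
    h_lp = signal.firwin(cfg.fir_taps, cfg.hp_cutoff_hz,
                         fs=t.fs, window="hamming")
    low = np.column_stack([_zero_phase_fir(t.xyz[:, k], h_lp) for k in range(3)])
    dyn = t.xyz - low
    static = t.xyz - dyn
    return t.replace_xyz(static), t.replace_xyz(dyn)


def extract_dive_clips(
    t: AccelTable,
    dive_times_s: list[float],
    cfg: MotionConfig = MotionConfig(),
) -> list[tuple[float, float]]:
    """2-minute windows centered on dive timepoints, clamped to the trace,
    with overlapping windows merged into single longer clips."""
    t0, t1 = float(t.t[0]), float(t.t[-1]) + 1.0 / t.fs
    for time_s in dive_times_s:
        if not t0 <= time_s < t1:
            raise ValueError(f"dive time {time_s}s outside trace [{t0}, {t1})")
    spans = sorted(
        (max(time_s - cfg.clip_half_width_s, t0),
         min(time_s + cfg.clip_half_width_s, t1))
        for time_s in dive_times_s
    )
    merged: list[tuple[float, float]] = []
    for start, stop in spans:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], stop))
        else:
            merged.append((start, stop))
    return merged


def split_low_amplitude(
    clip: AccelTable,
    cfg: MotionConfig = MotionConfig(),
    category: str = "dive",
    dynamic: AccelTable | None = None,
) -> list[Segment]:
    """Split a clip into active segments separated by quiet spans.

    Quiet spans are maximal runs of at least ``quiet_span_s`` where the
    dynamic-component vector magnitude stays below ``quiet_mag_g``
    (gravity keeps the *raw* magnitude near 1 g, so the dynamic component
    is the only channel on which the threshold is meaningful).  Active
    spans are retained iff strictly longer than ``min_segment_s``.
    """
    if dynamic is None:
        _, dynamic = decompose_static_dynamic(clip, cfg)
    mag = dynamic.magnitude()
    quiet = mag < cfg.quiet_mag_g
    min_run = int(round(cfg.quiet_span_s * clip.fs))
    n = len(quiet)
    separators: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if quiet[i]:
            j = i
            while j < n and quiet[j]:
                j += 1
            if j - i >= min_run:
                separators.append((i, j))
            i = j
        else:
            i += 1
    segments: list[Segment] = []
    prev = 0
    for s, e in separators + [(n, n)]:
        if s > prev:
            dur = (s - prev) / clip.fs
            if dur > cfg.min_segment_s:
                segments.append(
                    Segment(float(clip.t[prev]),
                            float(clip.t[prev] + dur),
                            category)
                )
        prev = e
    return segments


def detect_static_peaks(
    static_z: np.ndarray,
    fs: float,
    cfg: MotionConfig = MotionConfig(),
    t0: float = 0.0,
) -> list[float]:
    """Times of static-z peaks: local maxima at least ``peak_height_g`` high
    and ``peak_min_sep_samples`` apart (higher wins, then earlier)."""
    idx, _ = signal.find_peaks(
        np.asarray(static_z, dtype=float),
        height=cfg.peak_height_g,
        distance=cfg.peak_min_sep_samples,
    )
    return [t0 + i / fs for i in idx]


def attach_peaks(
    segments: list[Segment],
    static_z: np.ndarray,
    fs: float,
    cfg: MotionConfig = MotionConfig(),
    t0: float = 0.0,
) -> list[Segment]:
    """Detect peaks once over the clip and assign them to their segments."""
    peaks = detect_static_peaks(static_z, fs, cfg, t0)
    for seg in segments:
        seg.peak_times_s = [p for p in peaks if seg.start_s <= p < seg.stop_s]
    return segments


def classify_segments(segments: list[Segment]) -> ContingencyTable2x2:
    """Tally segments into the 2x2 table category x has-peak."""
    a = b = c = d = 0
    for seg in segments:
        if seg.category == "dive":
            if seg.has_peak:
                a += 1
            else:
                b += 1
        elif seg.category == "non_dive":
            if seg.has_peak:
                c += 1
            else:
                d += 1
        else:
            raise ValueError(f"unknown segment category {seg.category!r}")
    return ContingencyTable2x2(a, b, c, d)


def fisher_exact_two_sided(tbl: ContingencyTable2x2) -> float:
    """Exact two-sided Fisher p for a 2x2 table.

    With margins fixed, the first cell follows a hypergeometric law; the
    p-value sums the probabilities of every table (same margins) whose
    probability does not exceed the observed one (1e-12 relative slack for
    floating-point ties).  Computed in log space via ``gammaln``.
    """
    a, b, c, d = tbl.a, tbl.b, tbl.c, tbl.d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("degenerate table: a zero margin leaves nothing to test")
    n = r1 + r2

    def logp(k: int) -> float:
        # hypergeometric pmf of the top-left cell
        return (
            gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
            + gammaln(r2 + 1) - gammaln(c1 - k + 1) - gammaln(r2 - c1 + k + 1)
            - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
        )

    k_min = max(0, c1 - r2)
    k_max = min(r1, c1)
    lp_obs = logp(a)
    lps = [logp(k) for k in range(k_min, k_max + 1)]
    include = [lp for lp in lps if lp <= lp_obs + np.log1p(1e-12)]
    return float(min(np.exp(logsumexp(include)), 1.0))


def accel_spectrogram(
    series: np.ndarray,
    fs: float,
    cfg: MotionConfig = MotionConfig(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """STFT magnitude of one acceleration channel (Hann window, centered
    frames, zero padding at the edges).

    Returns (freqs 0..fs/2, frame center times, |STFT| of shape
    (nfft//2 + 1, n_frames)).
    """
    x = np.asarray(series, dtype=float)
    if len(x) < cfg.spec_win:
        raise ValueError(
            f"series of {len(x)} samples shorter than window {cfg.spec_win}"
        )
    win = signal.windows.hann(cfg.spec_win, sym=False)
    half = cfg.spec_win // 2
    padded = np.concatenate([np.zeros(half), x, np.zeros(half)])
    n_frames = 1 + (len(padded) - cfg.spec_win) // cfg.spec_hop
    mat = np.empty((cfg.spec_nfft // 2 + 1, n_frames))
    for k in range(n_frames):
        frame = padded[k * cfg.spec_hop: k * cfg.spec_hop + cfg.spec_win] * win
        mat[:, k] = np.abs(np.fft.rfft(frame, n=cfg.spec_nfft))
    freqs = np.fft.rfftfreq(cfg.spec_nfft, d=1.0 / fs)
    times = np.arange(n_frames) * cfg.spec_hop / fs
    return freqs, times, mat


def dive_discrimination(
    trace: AccelTable,
    dive_times_s: list[float],
    flight_spans: list[tuple[float, float]],
    cfg: MotionConfig = MotionConfig(),
) -> tuple[list[Segment], ContingencyTable2x2, float]:
    """End-to-end dive vs ordinary-flight comparison.

    Normalizes the trace, extracts merged 2-minute dive clips, decomposes
    each clip (and each supplied non-dive flight span), segments on quiet
    spans, detects static-z peaks, tallies the 2x2 table and returns the
    exact Fisher p.  Non-dive flight spans are supplied as labelled
    intervals (in the field they are found manually from audio cues).
    """
    norm = normalize_accel(trace)
    segments: list[Segment] = []
    for start, stop in extract_dive_clips(norm, dive_times_s, cfg):
        clip = norm.slice_time(start, stop)
        clip = normalize_accel(clip)  # per-clip field-strength normalization
        static, dynamic = decompose_static_dynamic(clip, cfg)
        segs = split_low_amplitude(clip, cfg, category="dive", dynamic=dynamic)
        segments.extend(
            attach_peaks(segs, static.az, clip.fs, cfg, t0=float(clip.t[0]))
        )
    for start, stop in flight_spans:
        clip = norm.slice_time(start, stop)
        clip = normalize_accel(clip)
        static, dynamic = decompose_static_dynamic(clip, cfg)
        segs = split_low_amplitude(clip, cfg, category="non_dive", dynamic=dynamic)
        segments.extend(
            attach_peaks(segs, static.az, clip.fs, cfg, t0=float(clip.t[0]))
        )
    table = classify_segments(segments)
    try:
        p = fisher_exact_two_sided(table)
    except ValueError:
        p = float("nan")
    return segments, table, p
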