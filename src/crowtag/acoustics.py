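"""Call level and signal-to-noise analysis.

A detected call's level is the RMS amplitude of the waveform over the
call's span, expressed in dB relative to digital full scale (dBFS, full
scale = amplitude 1.0, so a full-scale sine sits at -3.01 dBFS).  Its SNR
is that RMS divided by the RMS of the nearest contiguous noise window
(default 4 s) that contains no focal vocalization — non-focal and chick
calls count as noise, mirroring how a tag hears its surroundings.  Calls
with SNR above 60 dB are flagged as clipping artifacts and excluded.  No
denoising is applied anywhere in this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .formats_io import EventBox, SelectionTable


class NoNoiseWindowError(RuntimeError):
    """No qualifying noise window exists in the file."""


@dataclass(frozen=True)
class SNRConfig:
    """Thresholds and window sizes for the level/SNR pipeline.

    Probability thresholds are strict (a detection at exactly 0.5 is
    excluded); ``clip_snr_db`` is also strict (exactly 60 dB is kept).
    """

    det_prob_min: float = 0.5
    class_prob_min: float = 0.5
    noise_window_s: float = 4.0
    clip_snr_db: float = 60.0
    chick_sample_n: int = 100
    search_step_s: float = 0.1

    def __post_init__(self) -> None:
        for name in ("det_prob_min", "class_prob_min"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if self.noise_window_s <= 0:
            raise ValueError("noise_window_s must be positive")


@dataclass
class LevelRecord:
    """Per-call RMS amplitude and its dBFS level."""

    box: EventBox
    rms: float
    level_dbfs: float


@dataclass
class SNRRecord:
    """Per-call SNR estimate with the noise window that produced it."""

    box: EventBox
    signal_rms: float
    noise_rms: float
    snr_db: float
    noise_window: tuple[float, float]
    excluded_clipping: bool


def select_confident(
    predictions: SelectionTable,
    target_class: str,
    cfg: SNRConfig = SNRConfig(),
) -> SelectionTable:
    """Detections with detection_prob > det_prob_min and
    class_probs[target_class] > class_prob_min (both strict)."""
    kept = []
    for box in predictions:
        if box.class_probs is None:
            raise ValueError(
                f"box at {box.start_s}s has no class probabilities"
            )
        if (box.detection_prob > cfg.det_prob_min
                and box.class_probs.get(target_class, 0.0) > cfg.class_prob_min):
            kept.append(box)
    return predictions.with_rows(kept)


def _span_slice(wave: np.ndarray, sr: int, start_s: float, stop_s: float) -> np.ndarray:
    i0 = int(round(start_s * sr))
    i1 = int(round(stop_s * sr))
    return wave[i0:i1]


def measure_level_dbfs(wave: np.ndarray, sr: int, box: EventBox) -> LevelRecord:
    """RMS level over [start, stop) in dBFS (full scale = 1.0)."""
    span = _span_slice(wave, sr, box.start_s, box.stop_s)
    if len(span) < 2:
        raise ValueError(f"box [{box.start_s}, {box.stop_s}) spans < 2 samples")
    rms = float(np.sqrt(np.mean(span.astype(float) ** 2)))
    if rms == 0.0:
        raise ValueError(f"all-zero span [{box.start_s}, {box.stop_s}): level undefined")
    return LevelRecord(box=box, rms=rms, level_dbfs=20.0 * np.log10(rms))


def select_noise_window(
    box: EventBox,
    focal_boxes: SelectionTable | Sequence[EventBox],
    file_duration_s: float,
    cfg: SNRConfig = SNRConfig(),
) -> tuple[float, float]:
    """Nearest contiguous window of ``noise_window_s`` free of focal calls.

    Candidate windows slide outward from the target box in
    ``search_step_s`` increments on both sides; the feasible window with
    the smallest gap to the box wins, ties broken toward earlier time (the
    window ending at the box's start beats the one starting at its stop).
    The window may abut the box but never overlaps any focal box.
    """
    w = cfg.noise_window_s
    if file_duration_s < w:
        raise NoNoiseWindowError(
            f"file of {file_duration_s}s cannot host a {w}s window"
        )
    focal = [(b.start_s, b.stop_s) for b in focal_boxes]

    eps = 1e-9  # tolerate roundoff at exact abutment
    def feasible(start: float) -> bool:
        stop = start + w
        if start < -eps or stop > file_duration_s + eps:
            return False
        return all(stop <= s + eps or start >= e - eps for s, e in focal)

    max_gap = max(box.start_s, file_duration_s - box.stop_s)
    n_steps = int(np.ceil(max_gap / cfg.search_step_s)) + 1
    for k in range(n_steps + 1):
        gap = k * cfg.search_step_s
        before = box.start_s - gap - w
        if feasible(before):
            return (before, before + w)
        after = box.stop_s + gap
        if feasible(after):
            return (after, after + w)
    raise NoNoiseWindowError(
        f"no focal-free {w}s window near box [{box.start_s}, {box.stop_s})"
    )


def estimate_snr(
    wave: np.ndarray,
    sr: int,
    box: EventBox,
    focal_boxes: SelectionTable | Sequence[EventBox],
    cfg: SNRConfig = SNRConfig(),
) -> SNRRecord:
    """SNR = 20*log10(RMS over the call span / RMS over the noise window)."""
    file_dur = len(wave) / sr
    window = select_noise_window(box, focal_boxes, file_dur, cfg)
    sig = measure_level_dbfs(wave, sr, box).rms
    noise_span = _span_slice(wave, sr, *window)
    noise_rms = float(np.sqrt(np.mean(noise_span.astype(float) ** 2)))
    if noise_rms == 0.0:
        raise ValueError("all-zero noise window: SNR undefined")
    snr = 20.0 * np.log10(sig / noise_rms)
    return SNRRecord(
        box=box, signal_rms=sig, noise_rms=noise_rms, snr_db=snr,
        noise_window=window, excluded_clipping=snr > cfg.clip_snr_db,
    )


def filter_clipping(
    records: Iterable[SNRRecord], cfg: SNRConfig = SNRConfig()
) -> tuple[list[SNRRecord], list[SNRRecord]]:
    """Split records at the clipping threshold (strictly above is excluded)."""
    kept, excluded = [], []
    for rec in records:
        (excluded if rec.snr_db > cfg.clip_snr_db else kept).append(rec)
    return kept, excluded


def sample_chick_calls(
    detections: SelectionTable,
    per_day_n: int = 100,
    seed: int = 0,
    day_of: Callable[[EventBox], str] | None = None,
) -> SelectionTable:
    """Sample ``per_day_n`` calls per (individual, day) group, without
    replacement, from every group with at least that many detections.

    ``day_of`` maps a box to its calendar day; by default the box's
    ``file_id`` stands in for the recording day (one file per day).  Groups
    below the threshold contribute nothing.
    """
    if day_of is None:
        day_of = lambda b: str(b.file_id)
    groups: dict[tuple[str, str], list[EventBox]] = {}
    for box in detections:
        groups.setdefault((str(box.individual_id), day_of(box)), []).append(box)
    rng = np.random.default_rng(seed)
    sampled: list[EventBox] = []
    for key in sorted(groups):
        boxes = groups[key]
        if len(boxes) >= per_day_n:
            idx = rng.choice(len(boxes), size=per_day_n, replace=False)
            sampled.extend(boxes[i] for i in sorted(idx))
    return detections.with_rows(sampled)


def summarize_distribution(values: Sequence[float]) -> dict[str, float]:
    """Boxplot summary: quartiles (linear interpolation) and 1.5-IQR whisker
    bounds."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, med, q3 = np.percentile(arr, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(q1 - 1.5 * iqr),
        "whisker_high": float(q3 + 1.5 * iqr),
    }


def amplitude_density(
    levels_a: Sequence[float],
    levels_b: Sequence[float],
    grid_size: int = 512,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian-kernel densities of two dBFS samples on a shared grid.

    Each curve is renormalized to integrate to 1 over the grid
    (trapezoidal), so groups of different sizes are directly comparable.
    Returns (grid, density_a, density_b).
    """
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    span = max(hi - lo, 1.0)
    grid = np.linspace(lo - 0.2 * span, hi + 0.2 * span, grid_size)

    def density(x: np.ndarray) -> np.ndarray:
        if np.ptp(x) == 0:  # degenerate sample: narrow Gaussian at the value
            d = np.exp(-0.5 * ((grid - x[0]) / 0.5) ** 2)
        else:
            d = gaussian_kde(x)(grid)
        return d / np.trapezoid(d, grid)

    return grid, density(a), density(b)
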