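"""Seeded synthetic tag data with known ground truth.

Three generators emulate the data a tail-mounted crow biologger produces:

* :func:`generate_soundscape` — a mono waveform of harmonic call bursts over
  Gaussian background noise, optionally passed through the tag front-end's
  single-pole 500-Hz high-pass, with the exact ground-truth selection table;
* :func:`generate_detection_scenario` — an annotation table plus a degraded
  prediction table (boundary jitter, misses, spurious insertions, label
  flips) together with the per-class confusion an ideal evaluator must find,
  computed here by exhaustive matching as an independent oracle;
* :func:`generate_accel_trace` — a tri-axial acceleration trace with gravity,
  a steady wingbeat oscillation, slow banking excursions during dives,
  landing impulses and quiescent gaps, with ground-truth dive peak times and
  active-flight spans.

Every generator is deterministic under its spec's seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .formats_io import CLASSES, UNKNOWN_LABEL, AccelTable, EventBox, SelectionTable

#: RMS of a full-scale sine is 1/sqrt(2): -3.0103 dB below a full-scale
#: constant.  Call levels are specified by peak (sine-equivalent) dBFS, so
#: the measured RMS level of a generated call sits ~3 dB below its peak_dbfs.
SINE_CREST_DB = 20.0 * np.log10(np.sqrt(2.0))

#: Harmonic templates: fundamental (Hz) and relative harmonic amplitudes.
#: Fundamentals sit well above the 500-Hz tag front-end corner.
CALL_TEMPLATES: dict[str, tuple[float, tuple[float, ...]]] = {
    "adult": (1200.0, (1.0, 0.5, 0.25)),
    "chick": (1800.0, (1.0, 0.6, 0.3)),
    "cuckoo": (2300.0, (1.0, 0.45, 0.2)),
}


@dataclass(frozen=True)
class CallSpec:
    """One synthetic call: placement, level, label and spectral template."""

    onset_s: float
    duration_s: float
    peak_dbfs: float
    label: str = "Focal"
    template: str = "adult"

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("call duration must be positive")
        if not -80.0 <= self.peak_dbfs <= 0.0:
            raise ValueError(f"peak_dbfs outside [-80, 0]: {self.peak_dbfs}")
        if self.template not in CALL_TEMPLATES:
            raise ValueError(f"unknown template {self.template!r}")


@dataclass
class SoundscapeSpec:
    """Recipe for a synthetic soundscape.

    ``front_end_hp_hz`` emulates the tag's single-pole high-pass (-3 dB at
    500 Hz by default); set to None to disable.  The default sample rate is
    the tag's native 46875 Hz; tests use lower rates for speed.
    """

    duration_s: float
    sample_rate_hz: int = 46875
    noise_dbfs: float = -60.0
    calls: tuple[CallSpec, ...] = ()
    front_end_hp_hz: float | None = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.calls = tuple(
            c if isinstance(c, CallSpec) else CallSpec(*c) for c in self.calls
        )
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for c in self.calls:
            if c.onset_s < 0 or c.onset_s + c.duration_s > self.duration_s:
                raise ValueError(
                    f"call at {c.onset_s}s exceeds soundscape [0, {self.duration_s})"
                )


@dataclass
class DetectionScenarioSpec:
    """Recipe for a paired annotation/prediction scenario.

    ``n_events`` maps each class to its event count (an int applies to all
    four scored classes).  Boundary jitter is a fraction of each event's
    duration; miss/spurious/flip rates are per-event probabilities.
    """

    n_events: Mapping[str, int] | int = 20
    mean_duration_s: float = 0.33
    jitter_frac: float = 0.0
    miss_rate: float = 0.0
    spurious_rate: float = 0.0
    label_flip_rate: float = 0.0
    iou_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_events, int):
            self.n_events = {c: self.n_events for c in CLASSES}
        for c, n in self.n_events.items():
            if c not in CLASSES + (UNKNOWN_LABEL,):
                raise ValueError(f"unknown class {c!r}")
            if n < 0:
                raise ValueError("n_events must be >= 0")
        for name in ("miss_rate", "spurious_rate", "label_flip_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {v}")
        if self.mean_duration_s <= 0:
            raise ValueError("mean_duration_s must be positive")


@dataclass
class AccelScenarioSpec:
    """Recipe for a synthetic flight/dive acceleration trace.

    ``dive_events`` are (time_s, bank_peak_g, bank_width_s) triples: each
    adds a slow Gaussian banking excursion (FWHM = bank_width_s) that lifts
    the static z-channel to bank_peak_g.  ``quiet_gaps`` suppress the
    wingbeat.  The default wingbeat (5 Hz) is a free parameter of the
    generator, not a species estimate.
    """

    duration_s: float
    fs: float = 50.0
    wingbeat_hz: float = 5.0
    wingbeat_amp_g: float = 0.6
    dive_events: tuple[tuple[float, float, float], ...] = ()
    quiet_gaps: tuple[tuple[float, float], ...] = ()
    landing_impulses: tuple[float, ...] = ()
    gravity_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    noise_g: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs <= 2.0 * self.wingbeat_hz:
            raise ValueError("fs must exceed twice the wingbeat frequency")
        for t, _, w in self.dive_events:
            if not 0 <= t < self.duration_s:
                raise ValueError(f"dive event at {t}s outside trace")
            if w <= 0:
                raise ValueError("bank_width_s must be positive")
        for a, b in self.quiet_gaps:
            if not (0 <= a < b <= self.duration_s):
                raise ValueError(f"quiet gap [{a}, {b}) outside trace")
        for t in self.landing_impulses:
            if not 0 <= t < self.duration_s:
                raise ValueError(f"landing impulse at {t}s outside trace")
        g = np.linalg.norm(self.gravity_axis)
        if g == 0:
            raise ValueError("gravity_axis must be nonzero")


# ---------------------------------------------------------------------------
# Soundscape
# ---------------------------------------------------------------------------

def _call_burst(call: CallSpec, sr: int) -> np.ndarray:
    """A Tukey-windowed harmonic burst scaled so that its RMS equals
    peak_dbfs - 3.01 dB (sine-equivalent level)."""
    f0, harmonics = CALL_TEMPLATES[call.template]
    n = max(int(round(call.duration_s * sr)), 2)
    t = np.arange(n) / sr
    burst = np.zeros(n)
    for k, amp in enumerate(harmonics, start=1):
        f = k * f0
        if f < sr / 2:
            burst += amp * np.sin(2 * np.pi * f * t)
    burst *= signal.windows.tukey(n, alpha=0.25)
    rms = np.sqrt(np.mean(burst**2))
    if rms == 0:
        raise ValueError(
            f"call template {call.template!r} has no energy below Nyquist "
            f"({sr / 2:.0f} Hz)"
        )
    target_rms = 10.0 ** ((call.peak_dbfs - SINE_CREST_DB) / 20.0)
    burst *= target_rms / rms
    if np.max(np.abs(burst)) > 1.0:
        raise ValueError(
            f"call at {call.onset_s}s exceeds full scale "
            f"(peak sample {np.max(np.abs(burst)):.3f})"
        )
    return burst


def generate_soundscape(spec: SoundscapeSpec) -> tuple[np.ndarray, SelectionTable]:
    """Render a soundscape and its exact ground-truth selection table.

    Overlapping calls are permitted and sum.  The optional front-end
    high-pass is applied last, after all components are mixed.
    """
    sr = spec.sample_rate_hz
    n = int(round(spec.duration_s * sr))
    rng = np.random.default_rng(spec.seed)
    noise_rms = 10.0 ** (spec.noise_dbfs / 20.0)
    wave = rng.normal(0.0, noise_rms, n)
    rows = []
    for call in spec.calls:
        burst = _call_burst(call, sr)
        i0 = int(round(call.onset_s * sr))
        wave[i0:i0 + len(burst)] += burst[: n - i0]
        rows.append(
            EventBox(call.onset_s, call.onset_s + call.duration_s, call.label,
                     file_id="synthetic")
        )
    if spec.front_end_hp_hz is not None:
        b, a = signal.butter(1, spec.front_end_hp_hz, "highpass", fs=sr)
        wave = signal.lfilter(b, a, wave)
    return wave, SelectionTable(rows, source_path="synthetic")


# ---------------------------------------------------------------------------
# Detection scenarios
# ---------------------------------------------------------------------------

def _iou(a: tuple[float, float], b: tuple[float, float]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return inter / (max(a[1], b[1]) - min(a[0], b[0]))


def _exhaustive_match(
    ann: Sequence[tuple[float, float]],
    pred: Sequence[tuple[float, float]],
    threshold: float,
) -> list[tuple[int, int]]:
    """Optimal one-to-one matching by explicit enumeration.

    Splits the admissible-edge graph into connected components and, within
    each, enumerates every one-to-one assignment, keeping the one with the
    most pairs and, among those, the largest total IoU (deterministic
    lexicographic tie-break).  Independent of the assignment-solver route
    used by the evaluator, so it can serve as its oracle.
    """
    edges = {
        (i, j): _iou(a, p)
        for i, a in enumerate(ann)
        for j, p in enumerate(pred)
        if _iou(a, p) > threshold
    }
    # connected components over annotation/prediction nodes
    parent: dict[tuple[str, int], tuple[str, int]] = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    for (i, j) in edges:
        union(("a", i), ("p", j))
    comps: dict[tuple[str, int], list[tuple[str, int]]] = {}
    for (i, j) in edges:
        comps.setdefault(find(("a", i)), []).extend([("a", i), ("p", j)])
    result: list[tuple[int, int]] = []
    for members in comps.values():
        ai = sorted({m[1] for m in members if m[0] == "a"})
        pj = sorted({m[1] for m in members if m[0] == "p"})
        best: tuple[int, float, list[tuple[int, int]]] | None = None
        # enumerate assignments of predictions to annotations (or skip)
        def recurse(k: int, used: set[int], chosen: list[tuple[int, int]],
                    total: float) -> None:
            nonlocal best
            if k == len(pj):
                cand = (len(chosen), total, sorted(chosen))
                if best is None or (cand[0], cand[1]) > (best[0], best[1]) or (
                    (cand[0], cand[1]) == (best[0], best[1]) and cand[2] < best[2]
                ):
                    best = cand
                return
            j = pj[k]
            recurse(k + 1, used, chosen, total)  # leave prediction unmatched
            for i in ai:
                if i not in used and (i, j) in edges:
                    recurse(k + 1, used | {i}, chosen + [(i, j)],
                            total + edges[(i, j)])
        recurse(0, set(), [], 0.0)
        assert best is not None
        result.extend(best[2])
    return sorted(result)


def _expected_confusion(
    ann_boxes: Sequence[EventBox],
    pred_boxes: Sequence[EventBox],
    threshold: float,
) -> dict[str, dict[str, int]]:
    """Per-class TP/FP/FN by exhaustive matching, with neutral Unknowns."""
    pairs = _exhaustive_match(
        [(b.start_s, b.stop_s) for b in ann_boxes],
        [(b.start_s, b.stop_s) for b in pred_boxes],
        threshold,
    )
    counts = {c: {"tp": 0, "fp": 0, "fn": 0} for c in CLASSES}
    matched_a = {i for i, _ in pairs}
    matched_p = {j for _, j in pairs}
    for i, j in pairs:
        true, pred = ann_boxes[i].label, pred_boxes[j].label
        if true == UNKNOWN_LABEL or pred == UNKNOWN_LABEL:
            continue
        if true == pred:
            counts[true]["tp"] += 1
        else:
            counts[true]["fn"] += 1
            counts[pred]["fp"] += 1
    for i, b in enumerate(ann_boxes):
        if i not in matched_a and b.label != UNKNOWN_LABEL:
            counts[b.label]["fn"] += 1
    for j, b in enumerate(pred_boxes):
        if j not in matched_p and b.label != UNKNOWN_LABEL:
            counts[b.label]["fp"] += 1
    return counts


def _class_probs_for(label: str) -> dict[str, float]:
    probs = {c: 0.05 for c in CLASSES}
    probs[label] = 0.85
    return probs


def generate_detection_scenario(
    spec: DetectionScenarioSpec,
) -> tuple[SelectionTable, SelectionTable, dict[str, dict[str, int]]]:
    """Build an annotation table, a degraded prediction table and the
    expected per-class confusion.

    Events are laid out sequentially with gaps of 1-3 s so annotation boxes
    never overlap; durations are lognormal with median ``mean_duration_s``.
    Each annotation is missed with probability ``miss_rate``; survivors are
    jittered at both boundaries by ±``jitter_frac`` of their duration and
    label-flipped with probability ``label_flip_rate``; spurious predictions
    (expected count = spurious_rate × number of annotations) are inserted
    in random inter-event gaps.  The expected confusion is computed by the
    module's own exhaustive matcher, not by the evaluator under test.
    """
    rng = np.random.default_rng(spec.seed)
    labels = [c for c in spec.n_events for _ in range(spec.n_events[c])]
    rng.shuffle(labels)
    ann_boxes: list[EventBox] = []
    cursor = 1.0
    for label in labels:
        dur = float(spec.mean_duration_s * np.exp(rng.normal(0.0, 0.3)))
        ann_boxes.append(EventBox(cursor, cursor + dur, label, file_id="synthetic"))
        cursor += dur + float(rng.uniform(1.0, 3.0))
    file_len = cursor + 1.0

    pred_boxes: list[EventBox] = []
    for box in ann_boxes:
        if rng.random() < spec.miss_rate:
            continue
        dur = box.duration_s
        j = spec.jitter_frac
        start = box.start_s + float(rng.uniform(-j, j)) * dur
        stop = box.stop_s + float(rng.uniform(-j, j)) * dur
        if stop - start < 0.05 * dur:
            stop = start + 0.05 * dur
        label = box.label
        if label != UNKNOWN_LABEL and rng.random() < spec.label_flip_rate:
            label = str(rng.choice([c for c in CLASSES if c != label]))
        elif label == UNKNOWN_LABEL:
            label = str(rng.choice(CLASSES))
        pred_boxes.append(
            EventBox(max(start, 0.0), stop, label, detection_prob=1.0,
                     class_probs=_class_probs_for(label), file_id="synthetic")
        )
    n_spurious = rng.binomial(max(len(ann_boxes), 1), spec.spurious_rate)
    for _ in range(n_spurious):
        dur = float(spec.mean_duration_s * np.exp(rng.normal(0.0, 0.3)))
        start = float(rng.uniform(0.0, max(file_len - dur, 0.1)))
        label = str(rng.choice(CLASSES))
        pred_boxes.append(
            EventBox(start, start + dur, label, detection_prob=1.0,
                     class_probs=_class_probs_for(label), file_id="synthetic")
        )

    annotations = SelectionTable(ann_boxes, source_path="synthetic")
    predictions = SelectionTable(pred_boxes, source_path="synthetic")
    expected = _expected_confusion(
        list(annotations), list(predictions), spec.iou_threshold
    )
    return annotations, predictions, expected


# ---------------------------------------------------------------------------
# Acceleration traces
# ---------------------------------------------------------------------------

def generate_accel_trace(
    spec: AccelScenarioSpec,
) -> tuple[AccelTable, dict]:
    """Render a tri-axial acceleration trace and its ground truth.

    The trace is gravity (along ``gravity_axis``, magnitude 1 g) plus a
    z-dominant wingbeat sinusoid gated off inside quiet gaps, sub-3-Hz
    Gaussian banking bumps that lift z to each dive's ``bank_peak_g``,
    short landing impulses, and white sensor noise.  Ground truth contains
    the dive peak times and the constructed active (non-quiet) spans.
    """
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    rng = np.random.default_rng(spec.seed)
    g = np.asarray(spec.gravity_axis, dtype=float)
    g = g / np.linalg.norm(g)
    xyz = np.tile(g, (n, 1))

    # wingbeat: z-dominant with a smaller fore-aft component, gated by gaps
    gate = np.ones(n)
    for a, b in spec.quiet_gaps:
        gate[(t >= a) & (t < b)] = 0.0
    if spec.wingbeat_amp_g > 0:
        carrier = np.sin(2 * np.pi * spec.wingbeat_hz * t)
        xyz[:, 2] += spec.wingbeat_amp_g * carrier * gate
        xyz[:, 1] += 0.3 * spec.wingbeat_amp_g * np.sin(
            2 * np.pi * spec.wingbeat_hz * t + np.pi / 3
        ) * gate

    # banking excursions: slow Gaussian bumps raising z to bank_peak_g
    base_z = float(g[2])
    for time_s, peak_g, width_s in spec.dive_events:
        sigma = width_s / 2.3548  # width is FWHM
        xyz[:, 2] += (peak_g - base_z) * np.exp(-0.5 * ((t - time_s) / sigma) ** 2)

    # landing impulses: 0.1-s half-sine jolts on z
    for time_s in spec.landing_impulses:
        m = (t >= time_s) & (t < time_s + 0.1)
        xyz[m, 2] += 1.5 * np.sin(np.pi * (t[m] - time_s) / 0.1)

    xyz += rng.normal(0.0, spec.noise_g, size=(n, 3))

    # constructed active spans: complement of the quiet gaps
    edges = [0.0]
    for a, b in sorted(spec.quiet_gaps):
        edges.extend([a, b])
    edges.append(spec.duration_s)
    active = [
        (edges[i], edges[i + 1])
        for i in range(0, len(edges), 2)
        if edges[i + 1] - edges[i] > 0
    ]
    truth = {
        "dive_peak_times_s": [e[0] for e in spec.dive_events],
        "active_segments": active,
    }
    table = AccelTable(t, xyz[:, 0], xyz[:, 1], xyz[:, 2], spec.fs)
    return table, truth
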