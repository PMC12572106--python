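"""Readers and writers for every external representation the pipeline touches.

Formats handled: Raven-style selection tables (tab-delimited annotation
exports with begin/end times in seconds), mono WAV audio, columnar
tri-axial acceleration tables, flat detection tables with class
probabilities, and metrics output as JSON/TSV.

Conventions fixed here and used throughout the package:

* time is seconds from file start; intervals are half-open ``[start, stop)``;
  sample indexing is 0-based;
* audio samples are floats on a full scale of ``[-1, 1]`` (integer WAV data
  is scaled by ``1 / 2**(bits-1)``), which fixes the dBFS reference;
* acceleration is exchanged as plain CSV in units of g.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

#: The four scored caller classes, in canonical order.
CLASSES: tuple[str, ...] = ("Focal", "Non-focal", "Crow chick", "Cuckoo")

#: Label used for vocalizations whose caller could not be determined.
UNKNOWN_LABEL = "Unknown"

#: Every label a selection table may carry.
ALLOWED_LABELS: tuple[str, ...] = CLASSES + (UNKNOWN_LABEL,)

BEGIN_COL = "Begin Time (s)"
END_COL = "End Time (s)"

_DETECTION_PROB_COLS = {
    "Focal": "p_focal",
    "Non-focal": "p_nonfocal",
    "Crow chick": "p_chick",
    "Cuckoo": "p_cuckoo",
}


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


@dataclass(frozen=True)
class EventBox:
    """One annotated or predicted vocalization: a time interval plus a label.

    ``detection_prob`` is 1.0 for human annotations.  ``class_probs`` maps
    the four named classes to probabilities and is present only for model
    predictions; a prediction whose maximum class probability does not
    exceed 0.5 is labelled Unknown.
    """

    start_s: float
    stop_s: float
    label: str
    detection_prob: float = 1.0
    class_probs: Mapping[str, float] | None = None
    individual_id: str | None = None
    file_id: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.start_s) or not np.isfinite(self.stop_s):
            raise ValueError("event times must be finite")
        if self.start_s < 0:
            raise ValueError(f"start_s must be >= 0, got {self.start_s}")
        if not self.start_s < self.stop_s:
            raise ValueError(
                f"start_s must be < stop_s, got [{self.start_s}, {self.stop_s})"
            )
        if self.label not in ALLOWED_LABELS:
            raise ValueError(
                f"label {self.label!r} not in allowed set {ALLOWED_LABELS}"
            )
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ValueError(f"detection_prob outside [0, 1]: {self.detection_prob}")
        if self.class_probs is not None:
            total = 0.0
            for cls, p in self.class_probs.items():
                if cls not in CLASSES:
                    raise ValueError(f"class_probs key {cls!r} not a scored class")
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"class probability outside [0, 1]: {p}")
                total += p
            if total > 1.0 + 1e-9:
                raise ValueError(f"class probabilities sum to {total} > 1")

    @property
    def duration_s(self) -> float:
        return self.stop_s - self.start_s


@dataclass
class SelectionTable:
    """An ordered collection of event boxes from one or more audio files.

    Rows are kept sorted by ``(start_s, stop_s, label)`` so that all
    downstream computations are independent of the order rows arrived in.
    """

    rows: list[EventBox] = field(default_factory=list)
    source_path: str | None = None
    channel: int = 1

    def __post_init__(self) -> None:
        self.rows = sorted(
            self.rows, key=lambda b: (b.start_s, b.stop_s, b.label)
        )

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def __getitem__(self, i: int) -> EventBox:
        return self.rows[i]

    def with_rows(self, rows: Iterable[EventBox]) -> "SelectionTable":
        return SelectionTable(list(rows), source_path=self.source_path,
                              channel=self.channel)

    def file_ids(self) -> set[str | None]:
        return {b.file_id for b in self.rows}


@dataclass
class AccelTable:
    """Uniformly sampled tri-axial acceleration in units of g.

    Axis convention: positive x rightward, y forward, z upward.  ``t`` is
    monotone with a uniform step of ``1/fs`` seconds.
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        n = len(self.t)
        if not (len(self.ax) == len(self.ay) == len(self.az) == n):
            raise ValueError("t, ax, ay, az must have equal length")
        if n == 0:
            raise ValueError("empty acceleration table")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(np.abs(dt - 1.0 / self.fs) >= 1e-6):
                i = int(np.argmax(np.abs(dt - 1.0 / self.fs)))
                raise FormatError(
                    f"non-uniform sampling at row {i + 1}: "
                    f"dt={dt[i]:.9f} vs expected {1.0 / self.fs:.9f}"
                )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def xyz(self) -> np.ndarray:
        """(n, 3) array of the three axes."""
        return np.column_stack([self.ax, self.ay, self.az])

    def magnitude(self) -> np.ndarray:
        """Euclidean norm of the acceleration vector, per sample."""
        return np.sqrt(self.ax**2 + self.ay**2 + self.az**2)

    def replace_xyz(self, xyz: np.ndarray) -> "AccelTable":
        return AccelTable(self.t.copy(), xyz[:, 0], xyz[:, 1], xyz[:, 2], self.fs)

    def slice_time(self, start_s: float, stop_s: float) -> "AccelTable":
        """Samples with start_s <= t < stop_s."""
        m = (self.t >= start_s) & (self.t < stop_s)
        if not np.any(m):
            raise ValueError(f"no samples in [{start_s}, {stop_s})")
        return AccelTable(self.t[m], self.ax[m], self.ay[m], self.az[m], self.fs)


# ---------------------------------------------------------------------------
# Raven selection tables
# ---------------------------------------------------------------------------

def read_selection_table(
    path: str | Path,
    label_column: str = "Annotation",
    file_id: str | None = None,
    individual_id: str | None = None,
) -> SelectionTable:
    """Read a Raven-dialect tab-delimited selection table.

    Requires the columns ``Begin Time (s)``, ``End Time (s)`` and
    ``label_column``.  Frequency columns, if present, are ignored.  Labels
    outside the five allowed values raise a :class:`FormatError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (BEGIN_COL, END_COL, label_column):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    rows = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        raw = dict(zip(df.columns, rec))
        try:
            start = float(raw[BEGIN_COL])
            stop = float(raw[END_COL])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-numeric time on row {i}: {exc}") from exc
        label = raw[label_column]
        if label not in ALLOWED_LABELS:
            raise FormatError(
                f"{path}: row {i}: label {label!r} not in {ALLOWED_LABELS}"
            )
        try:
            rows.append(
                EventBox(start, stop, label, file_id=file_id,
                         individual_id=individual_id)
            )
        except ValueError as exc:
            raise FormatError(f"{path}: row {i}: {exc}") from exc
    return SelectionTable(rows, source_path=str(path))


def write_selection_table(
    table: SelectionTable, path: str | Path, label_column: str = "Annotation"
) -> Path:
    """Write a Raven-dialect TSV (Selection, View, Channel, begin/end, label).

    Rows are emitted in the table's canonical start-time order; times carry
    six decimals, matching Raven's export precision.
    """
    path = Path(path)
    cols = ["Selection", "View", "Channel", BEGIN_COL, END_COL, label_column]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for i, box in enumerate(table.rows, start=1):
            fh.write(
                f"{i}\tSpectrogram 1\t{table.channel}\t"
                f"{box.start_s:.6f}\t{box.stop_s:.6f}\t{box.label}\n"
            )
    return path


# ---------------------------------------------------------------------------
# Detection tables (flat TSV with class probabilities)
# ---------------------------------------------------------------------------

def read_detections(path: str | Path) -> SelectionTable:
    """Read a detections TSV with columns start_s, stop_s, label,
    detection_prob, p_focal, p_nonfocal, p_chick, p_cuckoo (and optionally
    file_id, individual_id)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = ["start_s", "stop_s", "label", "detection_prob"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    has_probs = all(c in df.columns for c in _DETECTION_PROB_COLS.values())
    rows = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        probs = None
        if has_probs:
            probs = {cls: float(rec[col]) for cls, col in _DETECTION_PROB_COLS.items()}
        try:
            rows.append(
                EventBox(
                    float(rec["start_s"]), float(rec["stop_s"]), str(rec["label"]),
                    detection_prob=float(rec["detection_prob"]),
                    class_probs=probs,
                    file_id=str(rec["file_id"]) if "file_id" in rec and pd.notna(rec.get("file_id")) else None,
                    individual_id=str(rec["individual_id"]) if "individual_id" in rec and pd.notna(rec.get("individual_id")) else None,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: row {i}: {exc}") from exc
    return SelectionTable(rows, source_path=str(path))


def write_detections(table: SelectionTable, path: str | Path) -> Path:
    path = Path(path)
    recs = []
    for box in table.rows:
        rec = {
            "start_s": f"{box.start_s:.6f}",
            "stop_s": f"{box.stop_s:.6f}",
            "label": box.label,
            "detection_prob": f"{box.detection_prob:.6f}",
        }
        probs = box.class_probs or {}
        for cls, col in _DETECTION_PROB_COLS.items():
            rec[col] = f"{probs.get(cls, 0.0):.6f}"
        if box.file_id is not None:
            rec["file_id"] = box.file_id
        if box.individual_id is not None:
            rec["individual_id"] = box.individual_id
        recs.append(rec)
    pd.DataFrame(recs).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# WAV audio
# ---------------------------------------------------------------------------

def read_audio(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a WAV file as float samples on a [-1, 1] full scale.

    Multi-channel files yield the first channel.  PCM integer data is scaled
    by ``1 / 2**(bits-1)``; float data is returned as stored.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except ValueError as exc:
        raise FormatError(f"{path}: unsupported WAV encoding: {exc}") from exc
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        wave = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        wave = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        wave = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        wave = data.astype(np.float64)
    else:
        raise FormatError(f"{path}: unsupported sample dtype {data.dtype}")
    return wave, int(rate)


def write_audio(
    path: str | Path, wave: np.ndarray, sample_rate: int, subtype: str = "pcm16"
) -> Path:
    """Write float samples in [-1, 1] as WAV (``pcm16`` or ``float32``)."""
    path = Path(path)
    wave = np.asarray(wave, dtype=np.float64)
    if subtype == "pcm16":
        clipped = np.clip(wave, -1.0, 32767.0 / 32768.0)
        data = np.round(clipped * 32768.0).astype(np.int16)
    elif subtype == "float32":
        data = wave.astype(np.float32)
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")
    wavfile.write(path, int(sample_rate), data)
    return path


# ---------------------------------------------------------------------------
# Acceleration tables
# ---------------------------------------------------------------------------

def read_accel_table(path: str | Path, fs: float | None = None) -> AccelTable:
    """Read a columnar acceleration CSV.

    Accepts either a 4-column header ``t,ax,ay,az`` (sampling rate inferred
    from the median time step, then validated for uniformity) or a 3-column
    ``ax,ay,az`` with ``fs`` supplied by the caller.
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if {"t", "ax", "ay", "az"}.issubset(cols):
        t = df["t"].to_numpy(dtype=float)
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise FormatError(
                    f"{path}: non-increasing timestamp at row {i + 2}"
                )
            fs_eff = 1.0 / float(np.median(dt))
        else:
            if fs is None:
                raise FormatError(f"{path}: single row requires explicit fs")
            fs_eff = fs
        return AccelTable(t, df["ax"], df["ay"], df["az"], fs_eff)
    if {"ax", "ay", "az"}.issubset(cols):
        if fs is None:
            raise FormatError(f"{path}: no time column; fs must be declared")
        n = len(df)
        t = np.arange(n) / fs
        return AccelTable(t, df["ax"], df["ay"], df["az"], fs)
    raise FormatError(f"{path}: header must contain t,ax,ay,az or ax,ay,az")


def write_accel_table(table: AccelTable, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {"t": table.t, "ax": table.ax, "ay": table.ay, "az": table.az}
    )
    df.to_csv(path, index=False, float_format="%.12g")
    return path


# ---------------------------------------------------------------------------
# Metrics output
# ---------------------------------------------------------------------------

def write_metrics_json(metrics: Mapping, path: str | Path) -> Path:
    """Write a metrics mapping (or dataclass) as JSON."""
    path = Path(path)
    if dataclasses.is_dataclass(metrics) and not isinstance(metrics, type):
        metrics = dataclasses.asdict(metrics)
    with open(path, "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def write_metrics_tsv(per_class: Mapping[str, Mapping[str, float]],
                      path: str | Path) -> Path:
    """Write per-class metric rows (class × metric columns) as TSV."""
    path = Path(path)
    df = pd.DataFrame.from_dict(per_class, orient="index")
    df.index.name = "class"
    df.to_csv(path, sep="\t")
    return path
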