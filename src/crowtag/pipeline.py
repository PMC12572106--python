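"""End-to-end orchestration: synth -> detect -> eval -> snr -> motion.

A single :class:`PipelineConfig` carries every stage's configuration and a
global seed; per-stage seeds are derived as ``seed + stage index`` so each
stage can be rerun independently.  All outputs are written through
formats_io and a manifest records the config hash and the seeds actually
used, making reruns bit-identical.

The detection stage is a simple short-window RMS energy detector: it marks
maximal runs where the 25-ms RMS exceeds a dBFS threshold, merges runs
separated by gaps shorter than 50 ms, and keeps runs of sufficient
duration.  It provides pipeline plumbing only — a stand-alone baseline, not
a trained vocalization classifier — so its boxes carry the Unknown label.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import acoustics, boxeval, formats_io, motion, synthgen
from .formats_io import UNKNOWN_LABEL, EventBox, SelectionTable

logger = logging.getLogger("crowtag")

STAGES = ("soundscape", "detect", "scenario", "snr", "accel")


@dataclass
class PipelineConfig:
    soundscape: synthgen.SoundscapeSpec = field(
        default_factory=lambda: synthgen.SoundscapeSpec(
            duration_s=30.0, sample_rate_hz=8000, noise_dbfs=-55.0,
            calls=tuple(
                synthgen.CallSpec(2.0 + 3.0 * i, 0.33, -12.0 - 3.0 * i, "Focal")
                for i in range(8)
            ),
        )
    )
    scenario: synthgen.DetectionScenarioSpec = field(
        default_factory=lambda: synthgen.DetectionScenarioSpec(
            n_events=20, jitter_frac=0.1, miss_rate=0.2,
            spurious_rate=0.2, label_flip_rate=0.1,
        )
    )
    accel: synthgen.AccelScenarioSpec = field(
        default_factory=lambda: synthgen.AccelScenarioSpec(
            duration_s=900.0,
            dive_events=((150.0, 2.2, 1.5), (420.0, 2.0, 1.2)),
            quiet_gaps=((60.0, 66.0), (230.0, 236.0), (340.0, 346.0),
                        (500.0, 506.0), (700.0, 706.0)),
            landing_impulses=(510.0,),
        )
    )
    eval_cfg: boxeval.EvalConfig = field(default_factory=boxeval.EvalConfig)
    snr_cfg: acoustics.SNRConfig = field(default_factory=acoustics.SNRConfig)
    motion_cfg: motion.MotionConfig = field(default_factory=motion.MotionConfig)
    detector_threshold_dbfs: float = -30.0
    detector_min_dur_s: float = 0.1
    seed: int = 0
    out_dir: str = "crowtag_out"
    log_level: str = "INFO"

    def stage_seed(self, stage: str) -> int:
        return self.seed + STAGES.index(stage)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, sub_cls in (
            ("soundscape", synthgen.SoundscapeSpec),
            ("scenario", synthgen.DetectionScenarioSpec),
            ("accel", synthgen.AccelScenarioSpec),
            ("eval_cfg", boxeval.EvalConfig),
            ("snr_cfg", acoustics.SNRConfig),
            ("motion_cfg", motion.MotionConfig),
        ):
            if key in raw:
                sub = dict(raw.pop(key))
                if key == "soundscape" and "calls" in sub:
                    sub["calls"] = tuple(
                        synthgen.CallSpec(**c) if isinstance(c, dict)
                        else synthgen.CallSpec(*c)
                        for c in sub["calls"]
                    )
                if key == "scenario" and isinstance(sub.get("n_events"), dict):
                    sub["n_events"] = dict(sub["n_events"])
                for tup_key in ("dive_events", "quiet_gaps", "landing_impulses",
                                "gravity_axis", "classes"):
                    if tup_key in sub and isinstance(sub[tup_key], list):
                        sub[tup_key] = tuple(
                            tuple(v) if isinstance(v, list) else v
                            for v in sub[tup_key]
                        )
                kwargs[key] = sub_cls(**sub)
        kwargs.update(raw)
        return cls(**kwargs)


def energy_detector(
    wave: np.ndarray,
    sample_rate: int,
    threshold_dbfs: float = -30.0,
    min_dur_s: float = 0.1,
    win_s: float = 0.025,
    merge_gap_s: float = 0.05,
) -> SelectionTable:
    """Short-window RMS threshold detector (plumbing baseline).

    Boxes are maximal runs where the ``win_s`` RMS exceeds
    ``threshold_dbfs``, merged across gaps shorter than ``merge_gap_s`` and
    kept if at least ``min_dur_s`` long; labels are Unknown with
    detection_prob 1.
    """
    if threshold_dbfs >= 0:
        raise ValueError("threshold must be below 0 dBFS")
    win = max(int(round(win_s * sample_rate)), 1)
    n_frames = len(wave) // win
    if n_frames == 0:
        return SelectionTable([])
    frames = wave[: n_frames * win].reshape(n_frames, win)
    rms = np.sqrt(np.mean(frames.astype(float) ** 2, axis=1))
    active = rms > 10.0 ** (threshold_dbfs / 20.0)
    runs: list[tuple[float, float]] = []
    i = 0
    while i < n_frames:
        if active[i]:
            j = i
            while j < n_frames and active[j]:
                j += 1
            runs.append((i * win / sample_rate, j * win / sample_rate))
            i = j
        else:
            i += 1
    merged: list[tuple[float, float]] = []
    for start, stop in runs:
        if merged and start - merged[-1][1] < merge_gap_s:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))
    boxes = [
        EventBox(start, stop, UNKNOWN_LABEL, detection_prob=1.0,
                 file_id="synthetic")
        for start, stop in merged
        if stop - start >= min_dur_s
    ]
    return SelectionTable(boxes)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage, write all artifacts, return the report dict.

    Artifacts: ground-truth and detected selection tables, soundscape WAV,
    evaluation metrics JSON/TSV, SNR table TSV, acceleration CSV, segments
    TSV, contingency + Fisher p JSON, and a manifest with the config hash
    and per-stage seeds.  Reruns with the same config are bit-identical.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    def stage(name: str):
        logger.info("stage %s (seed %d)", name, cfg.stage_seed(name))

    try:
        stage("soundscape")
        sspec = dataclasses.replace(cfg.soundscape, seed=cfg.stage_seed("soundscape"))
        wave, truth = synthgen.generate_soundscape(sspec)
        formats_io.write_audio(out / "soundscape.wav", wave,
                               sspec.sample_rate_hz, subtype="float32")
        formats_io.write_selection_table(truth, out / "ground_truth.txt")

        stage("detect")
        detections = energy_detector(
            wave, sspec.sample_rate_hz, cfg.detector_threshold_dbfs,
            cfg.detector_min_dur_s,
        )
        formats_io.write_detections(detections, out / "detections.tsv")
        det_match = boxeval.match_boxes(truth, detections, cfg.eval_cfg)
        det_counts = boxeval.detection_counts(det_match, truth, cfg.eval_cfg)
        p, r, f1, _ = boxeval._prf(det_counts.tp, det_counts.fp, det_counts.fn)
        report["detector"] = {"tp": det_counts.tp, "fp": det_counts.fp,
                              "fn": det_counts.fn, "precision": p,
                              "recall": r, "f1": f1}

        stage("scenario")
        dspec = dataclasses.replace(cfg.scenario, seed=cfg.stage_seed("scenario"))
        annotations, predictions, expected = synthgen.generate_detection_scenario(dspec)
        formats_io.write_selection_table(annotations, out / "annotations.txt")
        formats_io.write_detections(predictions, out / "predictions.tsv")
        metrics = boxeval.evaluate(annotations, predictions, cfg.eval_cfg)
        formats_io.write_metrics_json(metrics, out / "metrics.json")
        formats_io.write_metrics_tsv(metrics.per_class, out / "metrics.tsv")
        report["eval"] = {
            "macro_precision": metrics.macro_precision,
            "macro_recall": metrics.macro_recall,
            "macro_f1": metrics.macro_f1,
            "expected_confusion": expected,
        }

        stage("snr")
        focal = truth.with_rows(b for b in truth if b.label == "Focal")
        records = []
        for box in focal:
            try:
                records.append(
                    acoustics.estimate_snr(wave, sspec.sample_rate_hz, box,
                                           focal, cfg.snr_cfg)
                )
            except acoustics.NoNoiseWindowError as exc:
                logger.warning("snr: skipping box at %.2fs: %s", box.start_s, exc)
        kept, excluded = acoustics.filter_clipping(records, cfg.snr_cfg)
        rows = [
            {
                "start_s": f"{r.box.start_s:.6f}",
                "stop_s": f"{r.box.stop_s:.6f}",
                "snr_db": f"{r.snr_db:.4f}",
                "noise_start_s": f"{r.noise_window[0]:.6f}",
                "noise_stop_s": f"{r.noise_window[1]:.6f}",
                "excluded_clipping": r.excluded_clipping,
            }
            for r in records
        ]
        import pandas as pd
        pd.DataFrame(rows).to_csv(out / "snr.tsv", sep="\t", index=False)
        report["snr"] = {
            "n_records": len(records),
            "n_excluded_clipping": len(excluded),
            "summary": (acoustics.summarize_distribution([r.snr_db for r in kept])
                        if kept else None),
        }

        stage("accel")
        aspec = dataclasses.replace(cfg.accel, seed=cfg.stage_seed("accel"))
        trace, accel_truth = synthgen.generate_accel_trace(aspec)
        formats_io.write_accel_table(trace, out / "accel.csv")
        dive_times = accel_truth["dive_peak_times_s"]
        clips = motion.extract_dive_clips(trace, dive_times, cfg.motion_cfg)
        flight_spans = [
            s for s in accel_truth["active_segments"]
            if all(s[1] <= c0 or s[0] >= c1 for c0, c1 in clips)
            and s[1] - s[0] > cfg.motion_cfg.min_segment_s
        ]
        segments, table, p_value = motion.dive_discrimination(
            trace, dive_times, flight_spans, cfg.motion_cfg
        )
        pd.DataFrame(
            [
                {"start_s": s.start_s, "stop_s": s.stop_s,
                 "category": s.category, "has_peak": s.has_peak,
                 "peak_times_s": ";".join(f"{p:.3f}" for p in s.peak_times_s)}
                for s in segments
            ]
        ).to_csv(out / "segments.tsv", sep="\t", index=False)
        report["motion"] = {
            "contingency": {"a": table.a, "b": table.b,
                            "c": table.c, "d": table.d},
            "fisher_p": p_value,
        }
        formats_io.write_metrics_json(report["motion"], out / "motion.json")
    except Exception as exc:  # noqa: BLE001 — abort with stage context
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stage_seeds": {s: cfg.stage_seed(s) for s in STAGES},
        "config": cfg.to_dict(),
    }
    formats_io.write_metrics_json(manifest, out / "manifest.json")
    report["manifest"] = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    return report
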