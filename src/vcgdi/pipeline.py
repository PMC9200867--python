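"""End-to-end orchestration: ECG record → synchrony measurement.

One call chains the whole analysis: band-pass filter, polynomial detrend,
Kors reconstruction, peak detection, windowing + endpoint zeroing,
correlation QC, signal averaging, adaptive-threshold limit detection and the
VTI/STI integrals.  Batch helpers collect per-record measurements into a
DataFrame and report excluded recordings with their reasons.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import beats, limits, preprocessing
from .exceptions import QCError, VcgdiError
from .io import ECGRecord
from .synchrony import SynchronyMeasurement, compute_integrals
from .vcg import kors_transform


@dataclass
class PipelineConfig:
    """Tunable parameters of the signal pipeline (all units explicit)."""

    filter_order: int = 4
    filter_low_hz: float = 0.5
    filter_high_hz: float = 150.0
    detrend_poly_order: int = 10
    window_ms: float = beats.WINDOW_MS
    peak_min_separation_ms: float = beats.MIN_SEPARATION_MS
    peak_min_relative_height: float = beats.MIN_RELATIVE_HEIGHT
    qc_correlation_threshold: float = beats.QC_CORRELATION_THRESHOLD
    qc_mode: str = "pairwise"
    limits_step_mv: float = limits.STEP_MV
    limits_poly_order: int = limits.POLY_ORDER
    limits_derivative_criterion: float = limits.DERIVATIVE_CRITERION
    limits_method: str = "poly"
    limits_fallback: bool = True
    preprocess: bool = True

    def to_file(self, path: str | Path) -> None:
        lines = [f"{k} = {v}" for k, v in dataclasses.asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        for ln in Path(path).read_text().splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            key, _, val = ln.partition("=")
            key, val = key.strip(), val.strip()
            if key not in fields:
                raise VcgdiError(f"unknown config key {key!r}")
            typ = fields[key]
            if typ in ("int", int):
                kwargs[key] = int(val)
            elif typ in ("float", float):
                kwargs[key] = float(val)
            elif typ in ("bool", bool):
                kwargs[key] = val.lower() in ("1", "true", "yes", "on")
            else:
                kwargs[key] = val
        return cls(**kwargs)


def analyze_record(record: ECGRecord,
                   config: PipelineConfig | None = None) -> SynchronyMeasurement:
    """Run the full pipeline on one record.

    Raises :class:`QCError` when the recording must be excluded (no usable
    beats, or beat-to-beat correlation below the threshold).  The returned
    measurement has no dyssynchrony index yet — scoring needs a fitted
    control line (see :meth:`ControlLineResults.score`).
    """
    cfg = config or PipelineConfig()
    rec = record
    if cfg.preprocess:
        rec = preprocessing.bandpass_filter(
            rec, order=cfg.filter_order,
            low=cfg.filter_low_hz, high=cfg.filter_high_hz)
        rec = preprocessing.remove_baseline(rec, poly_order=cfg.detrend_poly_order)
    vcg = kors_transform(rec)
    peaks = beats.detect_peaks(
        vcg.voltage, vcg.sampling_rate,
        min_separation_ms=cfg.peak_min_separation_ms,
        min_relative_height=cfg.peak_min_relative_height,
        edge_margin_ms=cfg.window_ms / 2)
    ensemble = beats.extract_windows(vcg, peaks, window_ms=cfg.window_ms)
    qc = beats.qc_correlation(ensemble, threshold=cfg.qc_correlation_threshold,
                              mode=cfg.qc_mode)
    avg = beats.average_beats(ensemble, threshold=cfg.qc_correlation_threshold,
                              mode=cfg.qc_mode)
    segment, _curve = limits.detect_limits(
        avg, step=cfg.limits_step_mv, poly_order=cfg.limits_poly_order,
        criterion=cfg.limits_derivative_criterion,
        method=cfg.limits_method, fallback=cfg.limits_fallback)
    vti, sti = compute_integrals(avg, segment)
    return SynchronyMeasurement(
        patient_id=record.patient_id,
        vti=vti, sti=sti,
        qrs_duration_ms=segment.duration_ms,
        threshold_mv=segment.threshold_mv,
        n_beats=avg.n_beats,
        min_correlation=qc.min_correlation,
        label=record.label,
    )


def analyze_records(records, config: PipelineConfig | None = None
                    ) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Batch analysis; returns (measurement table, [(patient_id, reason)...])."""
    rows, excluded = [], []
    for rec in records:
        try:
            rows.append(dataclasses.asdict(analyze_record(rec, config)))
        except QCError as exc:
            excluded.append((rec.patient_id, exc.reason))
    columns = [f.name for f in dataclasses.fields(SynchronyMeasurement)]
    df = pd.DataFrame(rows, columns=columns)
    return df, excluded
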