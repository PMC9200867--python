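"""Beat detection, windowing, endpoint correction, QC and signal averaging.

The ventricular-depolarization peaks are found on the spatial voltage series.
A 220-ms window (110 ms on each side of the peak) is cut from the X/Y/Z leads
for each beat; a straight line through each axis' own first and last sample is
subtracted so that window endpoints are exactly zero (the P-R and S-T segments
are isoelectric, so any residual there is offset/drift, not signal).  Windows
are peak-aligned by construction and ensemble-averaged after a beat-to-beat
correlation gate: recordings whose voltage windows correlate below 0.9
(minimum pairwise Pearson r, inclusive) are excluded — this is what removes
low signal-to-noise recordings and extrasystolic beats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .exceptions import ParameterError, QCError
from .vcg import VCGSignal, compute_speed, compute_voltage

#: Full analysis window around each voltage peak, ms.
WINDOW_MS = 220.0
#: Minimum peak separation (physiological refractory period), ms.
MIN_SEPARATION_MS = 300.0
#: Peaks must exceed this fraction of the global voltage maximum.
MIN_RELATIVE_HEIGHT = 0.4
#: Inclusive pass threshold for the pairwise window correlation.
QC_CORRELATION_THRESHOLD = 0.9


@dataclass
class QCResult:
    passed: bool
    min_correlation: float
    mean_correlation: float
    threshold: float
    mode: str = "pairwise"


@dataclass
class BeatEnsemble:
    """Peak-aligned, endpoint-zeroed beat windows from one recording.

    ``xyz`` has shape (n_beats, 3, window_len); ``voltage`` is recomputed from
    the corrected X/Y/Z so the norm identity holds inside every window.
    """

    xyz: np.ndarray
    voltage: np.ndarray
    peak_indices: np.ndarray
    sampling_rate: float
    qc: QCResult | None = field(default=None)

    @property
    def n_beats(self) -> int:
        return self.xyz.shape[0]

    @property
    def window_len(self) -> int:
        return self.xyz.shape[2]

    @property
    def peak_offset(self) -> int:
        """In-window sample index shared by every aligned peak."""
        return (self.window_len - 1) // 2


@dataclass
class AverageBeat:
    """Ensemble mean of the aligned windows, with voltage and speed recomputed
    from the averaged X/Y/Z (not averaged per beat — the norm is nonlinear)."""

    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray
    voltage: np.ndarray
    speed: np.ndarray
    n_beats: int
    sampling_rate: float

    @property
    def window_ms(self) -> float:
        return (len(self.voltage) - 1) / self.sampling_rate * 1000.0

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(len(self.voltage)) / self.sampling_rate * 1000.0


def detect_peaks(voltage: np.ndarray, sampling_rate: float,
                 min_separation_ms: float = MIN_SEPARATION_MS,
                 min_relative_height: float = MIN_RELATIVE_HEIGHT,
                 edge_margin_ms: float = WINDOW_MS / 2) -> np.ndarray:
    """Locate ventricular-depolarization peaks on the voltage series.

    Local maxima above ``min_relative_height`` × the global maximum, at least
    ``min_separation_ms`` apart (the larger peak wins inside any refractory
    span); peaks closer than ``edge_margin_ms`` to either record edge are
    dropped because their full window cannot be extracted.
    """
    voltage = np.asarray(voltage, dtype=float)
    if voltage.size < 2 * sampling_rate:
        raise ParameterError("need at least 2 s of signal for peak detection")
    vmax = voltage.max()
    if vmax <= 0:
        raise QCError("insufficient beats: flat voltage signal")
    distance = max(1, int(round(min_separation_ms * sampling_rate / 1000.0)))
    peaks, _ = find_peaks(voltage, height=min_relative_height * vmax,
                          distance=distance)
    margin = int(round(edge_margin_ms * sampling_rate / 1000.0))
    peaks = peaks[(peaks >= margin) & (peaks < voltage.size - margin)]
    if peaks.size < 2:
        raise QCError("insufficient beats: fewer than 2 usable peaks")
    return peaks


def endpoint_correct(window_xyz: np.ndarray) -> np.ndarray:
    """Zero a window's endpoints by removing each axis' own baseline tilt.

    From each of X, Y, Z the straight line through that axis' first and last
    sample is subtracted; both endpoints become exactly zero and the operation
    is idempotent.
    """
    window_xyz = np.asarray(window_xyz, dtype=float)
    n = window_xyz.shape[-1]
    if n < 2:
        raise ParameterError("window too short for endpoint correction")
    ramp = np.arange(n) / (n - 1)
    first = window_xyz[..., :1]
    last = window_xyz[..., -1:]
    return window_xyz - (first + (last - first) * ramp)


def extract_windows(vcg: VCGSignal, peaks: np.ndarray,
                    window_ms: float = WINDOW_MS) -> BeatEnsemble:
    """Cut an endpoint-corrected ``window_ms`` window around each voltage peak.

    Peaks too close to a record edge for a full window are silently excluded;
    fewer than 2 surviving beats raises :class:`QCError`.
    """
    fs = vcg.sampling_rate
    half = int(round(window_ms / 2 * fs / 1000.0))
    n = len(vcg.voltage)
    keep = [p for p in np.asarray(peaks, dtype=int) if p - half >= 0 and p + half < n]
    if len(keep) < 2:
        raise QCError("insufficient beats: fewer than 2 full windows")
    xyz_full = vcg.xyz
    windows = np.stack([xyz_full[:, p - half : p + half + 1] for p in keep])
    windows = endpoint_correct(windows)
    voltage = np.sqrt((windows**2).sum(axis=1))
    return BeatEnsemble(
        xyz=windows,
        voltage=voltage,
        peak_indices=np.asarray(keep, dtype=int),
        sampling_rate=fs,
    )


def qc_correlation(ensemble: BeatEnsemble,
                   threshold: float = QC_CORRELATION_THRESHOLD,
                   mode: str = "pairwise") -> QCResult:
    """Beat-to-beat Pearson correlation gate on the voltage windows.

    ``mode='pairwise'`` (default, the stricter reading) uses the minimum over
    all window pairs; ``mode='to_average'`` correlates each window with the
    ensemble mean.  The pass rule is inclusive: min r ≥ threshold passes.
    """
    if ensemble.n_beats < 2:
        raise ParameterError("QC needs at least 2 windows")
    if mode == "pairwise":
        r = np.corrcoef(ensemble.voltage)
        off = r[np.triu_indices(ensemble.n_beats, k=1)]
    elif mode == "to_average":
        mean = ensemble.voltage.mean(axis=0)
        off = np.array([np.corrcoef(w, mean)[0, 1] for w in ensemble.voltage])
    else:
        raise ParameterError(f"unknown QC mode {mode!r}")
    off = np.nan_to_num(off, nan=0.0)  # a flat window correlates with nothing
    result = QCResult(
        passed=bool(off.min() >= threshold),
        min_correlation=float(off.min()),
        mean_correlation=float(off.mean()),
        threshold=threshold,
        mode=mode,
    )
    ensemble.qc = result
    return result


def average_beats(ensemble: BeatEnsemble,
                  threshold: float = QC_CORRELATION_THRESHOLD,
                  mode: str = "pairwise",
                  enforce_qc: bool = True) -> AverageBeat:
    """Sample-wise mean of the aligned X/Y/Z windows.

    Runs (or reuses) the correlation QC first and refuses a failed ensemble
    unless ``enforce_qc`` is disabled.  Voltage and speed are recomputed from
    the averaged axes.
    """
    qc = ensemble.qc
    if qc is None or qc.threshold != threshold or qc.mode != mode:
        qc = qc_correlation(ensemble, threshold=threshold, mode=mode)
    if enforce_qc and not qc.passed:
        raise QCError(
            f"low signal correlation: min pairwise r = {qc.min_correlation:.3f} "
            f"< {threshold}"
        )
    mean_xyz = ensemble.xyz.mean(axis=0)
    X, Y, Z = mean_xyz
    return AverageBeat(
        X=X, Y=Y, Z=Z,
        voltage=compute_voltage(X, Y, Z),
        speed=compute_speed(X, Y, Z, ensemble.sampling_rate),
        n_beats=ensemble.n_beats,
        sampling_rate=ensemble.sampling_rate,
    )
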