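"""Adaptive-threshold detection of ventricular-depolarization limits.

The onset and offset of the averaged depolarization signal are found by
sweeping a voltage threshold upward in 0.001-mV steps over the averaged
voltage window.  At each threshold the duration of the contiguous
supra-threshold run containing the peak is recorded; the resulting
length-vs-threshold curve is fitted with a 7th-order polynomial, and the
patient-specific threshold is the first one at which the normalized first
derivative of that curve rises to the criterion value (default −0.275 per mV)
after the initial steep descent — i.e. the point where the curve stops
collapsing through the low-amplitude flanks (P/T-wave tails, residual noise)
and settles onto the depolarization complex proper.

Normalization of the derivative (pinned here, configurable): the slope
dL/dθ is multiplied by peak_mV/window_ms, which makes the initial flank
descent O(−1) for any beat amplitude.  Equivalently, the raw-slope
criterion is −0.275 × window/peak ≈ −60 ms/mV for a 1-mV, 220-ms beat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial
from scipy.interpolate import CubicSpline

from .beats import AverageBeat
from .exceptions import ParameterError

#: Threshold grid resolution, mV.
STEP_MV = 0.001
#: Sweep cap as a fraction of the peak voltage (avoids degenerate zero-length fits).
SWEEP_CAP = 0.95
#: Polynomial order of the length-vs-threshold fit.
POLY_ORDER = 7
#: Normalized-derivative criterion, per mV.
DERIVATIVE_CRITERION = -0.275


@dataclass
class ThresholdCurve:
    """Supra-threshold signal length as a function of the voltage threshold."""

    thresholds: np.ndarray          # mV grid, 0 .. SWEEP_CAP * peak
    lengths: np.ndarray             # ms, contiguous run containing the peak
    peak_mv: float
    window_ms: float
    poly: Polynomial | None = None  # 7th-order fit, set by fit_length_curve
    fit_rms_ms: float | None = None


@dataclass
class DepolarizationSegment:
    """Onset/offset of the depolarization signal within the 220-ms window."""

    onset_ms: float
    offset_ms: float
    threshold_mv: float

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


def _run_limits(voltage: np.ndarray, sampling_rate: float,
                threshold: float) -> tuple[float, float]:
    """Interpolated limits (ms) of the supra-threshold run containing the peak."""
    v = voltage
    p = int(np.argmax(v))
    dt_ms = 1000.0 / sampling_rate

    left = np.nonzero(v[: p + 1] < threshold)[0]
    if left.size == 0:
        onset = 0.0
    else:
        i = left[-1]
        # crossing between samples i (below) and i+1 (at/above)
        onset = (i + (threshold - v[i]) / (v[i + 1] - v[i])) * dt_ms

    right = np.nonzero(v[p:] < threshold)[0]
    if right.size == 0:
        offset = (v.size - 1) * dt_ms
    else:
        j = p + right[0]
        offset = (j - 1 + (v[j - 1] - threshold) / (v[j - 1] - v[j])) * dt_ms
    return onset, offset


def segment_limits(avg_voltage: np.ndarray | AverageBeat, threshold: float,
                   sampling_rate: float | None = None) -> DepolarizationSegment:
    """Locate depolarization onset/offset at a given threshold.

    Limits are the first and last point of the contiguous supra-threshold run
    containing the voltage peak, with linear interpolation between bracketing
    samples for sub-sample precision.
    """
    if isinstance(avg_voltage, AverageBeat):
        sampling_rate = avg_voltage.sampling_rate
        avg_voltage = avg_voltage.voltage
    if sampling_rate is None:
        raise ParameterError("sampling_rate required with a bare voltage array")
    v = np.asarray(avg_voltage, dtype=float)
    if threshold >= v.max():
        raise ParameterError("threshold must lie below the voltage peak")
    onset, offset = _run_limits(v, sampling_rate, threshold)
    return DepolarizationSegment(onset_ms=onset, offset_ms=offset,
                                 threshold_mv=float(threshold))


def upsample_voltage(voltage: np.ndarray, sampling_rate: float,
                     factor: int) -> tuple[np.ndarray, float]:
    """Sub-sample interpolation of an averaged voltage window.

    Cubic-spline interpolation recovers the smooth curve between samples,
    so the supra-threshold length curve loses the staircase quantization
    that raw sampling imposes near the detection criterion (a spline tracks
    a smooth, not-necessarily-band-limited pulse with less ringing than
    sinc reconstruction).  Values are clipped at zero (the voltage is a
    norm).
    """
    if factor == 1:
        return voltage, sampling_rate
    x = np.arange(voltage.size)
    xs = np.arange((voltage.size - 1) * factor + 1) / factor
    up = CubicSpline(x, voltage)(xs)
    return np.clip(up, 0.0, None), sampling_rate * factor


def threshold_sweep(avg_voltage: np.ndarray | AverageBeat,
                    sampling_rate: float | None = None,
                    step: float = STEP_MV,
                    cap: float = SWEEP_CAP,
                    upsample: int = 1) -> ThresholdCurve:
    """Sweep the threshold grid and record the supra-threshold signal length.

    The grid runs from 0 to ``cap`` × peak in ``step`` increments.  At θ = 0
    the whole (endpoint-zeroed) window is supra-threshold, so the first length
    equals the window duration; lengths are non-increasing in θ by
    construction of the contiguous-run rule.  ``upsample`` > 1 applies
    :func:`upsample_voltage` first (used by the full detector; leave at 1 for
    exact behaviour on analytically-defined pulses).
    """
    if isinstance(avg_voltage, AverageBeat):
        sampling_rate = avg_voltage.sampling_rate
        avg_voltage = avg_voltage.voltage
    if sampling_rate is None:
        raise ParameterError("sampling_rate required with a bare voltage array")
    v = np.asarray(avg_voltage, dtype=float)
    v, sampling_rate = upsample_voltage(v, sampling_rate, upsample)
    peak = float(v.max())
    if peak <= 10 * step:
        raise ParameterError("no peak: signal is flat relative to the step size")
    grid = np.arange(0.0, cap * peak + step / 2, step)
    lengths = np.empty_like(grid)
    for i, theta in enumerate(grid):
        onset, offset = _run_limits(v, sampling_rate, theta)
        lengths[i] = offset - onset
    return ThresholdCurve(
        thresholds=grid,
        lengths=lengths,
        peak_mv=peak,
        window_ms=(v.size - 1) * 1000.0 / sampling_rate,
    )


def fit_length_curve(curve: ThresholdCurve,
                     poly_order: int = POLY_ORDER) -> ThresholdCurve:
    """Least-squares polynomial fit of length (ms) against threshold (mV).

    ``Polynomial.fit`` maps the threshold axis to [-1, 1] internally, which
    keeps the 7th-order normal equations well conditioned; the returned
    polynomial evaluates in mV.  The RMS residual is stored on the curve.
    """
    if curve.thresholds.size < 20:
        raise ParameterError("need at least 20 grid points for the polynomial fit")
    poly = Polynomial.fit(curve.thresholds, curve.lengths, poly_order)
    resid = curve.lengths - poly(curve.thresholds)
    curve.poly = poly
    curve.fit_rms_ms = float(np.sqrt(np.mean(resid**2)))
    return curve


def normalized_length_derivative(curve: ThresholdCurve,
                                 method: str = "poly") -> np.ndarray:
    """dL/dθ on the grid, normalized by (window duration / peak voltage).

    Dividing the slope by window_ms/peak_mV makes the initial flank descent
    of any averaged beat O(−1) regardless of its amplitude, so one criterion
    value applies across patients; the printed ms/mV value corresponds to
    the raw slope −criterion × window/peak.

    ``method='poly'`` differentiates the 7th-order fit; ``method='raw'``
    takes span-limited finite differences of the raw length curve (the
    brute-force route, used as an independent cross-check of the polynomial
    one).
    """
    if curve.window_ms <= 0 or curve.peak_mv <= 0:
        raise ParameterError("degenerate length curve")
    if method == "poly":
        if curve.poly is None:
            fit_length_curve(curve)
        deriv = curve.poly.deriv()(curve.thresholds)
    elif method == "raw":
        # central differences with a small span: the length curve is
        # piecewise linear at grid resolution, so adjacent differences
        # produce a staircase; a ±4-step baseline reads the local slope
        # without any model fitting
        L, th = curve.lengths, curve.thresholds
        span = min(4, (L.size - 1) // 2)
        deriv = np.empty_like(L)
        deriv[span:-span] = (L[2 * span :] - L[: -2 * span]) / (
            th[2 * span :] - th[: -2 * span])
        deriv[:span] = (L[span] - L[0]) / (th[span] - th[0])
        deriv[-span:] = (L[-1] - L[-1 - span]) / (th[-1] - th[-1 - span])
    else:
        raise ParameterError(f"unknown derivative method {method!r}")
    return deriv * curve.peak_mv / curve.window_ms


def find_threshold(curve: ThresholdCurve,
                   criterion: float = DERIVATIVE_CRITERION,
                   method: str = "poly",
                   fallback: bool = True) -> float:
    """Patient-specific threshold from the normalized length-curve derivative.

    Returns the smallest grid threshold at which the normalized derivative
    rises back to (or above) ``criterion`` after the initial steep descent,
    i.e. after the derivative has first dipped below the criterion.  If the
    derivative never goes below the criterion it is met immediately and the
    first grid threshold is returned.  If it dips below and never recovers,
    the fallback returns the threshold where the derivative is maximal (the
    flattest point of the descent); with ``fallback=False`` that case raises.
    """
    g = normalized_length_derivative(curve, method=method)
    return float(curve.thresholds[_criterion_index(g, criterion, fallback)])


def _criterion_index(g: np.ndarray, criterion: float, fallback: bool) -> int:
    below = np.nonzero(g < criterion)[0]
    if below.size == 0:
        return 0                       # criterion met immediately
    recovered = np.nonzero(g[below[0]:] >= criterion)[0]
    if recovered.size:
        return int(below[0] + recovered[0])
    if fallback:
        return int(np.argmax(g))
    raise ParameterError(
        f"threshold not found: normalized derivative never recovers to {criterion}"
    )


#: Band-limited upsampling factor used by the full detector.
UPSAMPLE = 8


def detect_limits(beat: AverageBeat,
                  step: float = STEP_MV,
                  poly_order: int = POLY_ORDER,
                  criterion: float = DERIVATIVE_CRITERION,
                  method: str = "poly",
                  fallback: bool = True,
                  upsample: int = UPSAMPLE
                  ) -> tuple[DepolarizationSegment, ThresholdCurve]:
    """Full limit detection on an averaged beat: sweep, fit, threshold, segment."""
    v, fs = upsample_voltage(beat.voltage, beat.sampling_rate, upsample)
    curve = threshold_sweep(v, fs, step=step)
    fit_length_curve(curve, poly_order=poly_order)
    theta = find_threshold(curve, criterion=criterion, method=method,
                           fallback=fallback)
    segment = segment_limits(v, theta, sampling_rate=fs)
    return segment, curve
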