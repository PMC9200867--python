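"""Dyssynchrony index, control-line model, cutoff analysis and TPS-SD.

Scientific core of the package.  Over the detected depolarization segment two
integrals summarize each recording:

* ``VTI`` (voltage time integral, mV·ms) — area under the spatial voltage
  curve, the quantity known in the literature as QRS area;
* ``STI`` (speed time integral, mV) — integral of the dipole speed (mV/s)
  over the segment's time axis in ms, i.e. 10³ × the 3-D path length of the
  VCG loop.

In individuals without intraventricular conduction abnormalities STI is
proportional to VTI.  After nondimensionalizing VTI by 100 mV·ms and STI by
10,000 mV, an ordinary least-squares line ``sti_n = k + m·vti_n`` is fitted
to a control population (:class:`ControlLine`); the dyssynchrony index of any
recording is its normalized perpendicular distance to that line:

    index = |k + m·vti_n − sti_n| / sqrt(1 + m²)

A Youden-optimal cutoff on the index separates electrically dyssynchronous
patterns (LBBB, ventricular pacing) from the rest (:class:`YoudenCutoff`),
and :func:`tps_sd` computes the echocardiographic mechanical-dyssynchrony
statistic from an exported 18-segment time–strain table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .beats import AverageBeat
from .exceptions import ParameterError
from .io import StrainTable, load_json, save_json
from .limits import DepolarizationSegment

#: Nondimensionalization constants: VTI / 100 mV·ms, STI / 10,000 mV.
NORM_VTI = 100.0
NORM_STI = 10_000.0


@dataclass
class SynchronyMeasurement:
    """VTI, STI and derived quantities for one recording."""

    patient_id: str
    vti: float                    # mV·ms
    sti: float                    # mV
    qrs_duration_ms: float
    threshold_mv: float
    n_beats: int
    min_correlation: float
    label: str | None = None
    index: float | None = None    # filled once a control line is available


def compute_integrals(beat: AverageBeat,
                      segment: DepolarizationSegment) -> tuple[float, float]:
    """Trapezoidal VTI (mV·ms) and STI (mV) between segment onset and offset.

    The sub-sample segment limits are honoured by linear interpolation of the
    voltage and speed series at the exact onset/offset times.
    """
    if not segment.offset_ms > segment.onset_ms:
        raise ParameterError("zero-length depolarization segment")
    t = beat.time_ms
    if segment.onset_ms < t[0] - 1e-9 or segment.offset_ms > t[-1] + 1e-9:
        raise ParameterError("segment lies outside the beat window")
    inner = t[(t > segment.onset_ms) & (t < segment.offset_ms)]
    nodes = np.concatenate(([segment.onset_ms], inner, [segment.offset_ms]))
    vti = float(np.trapezoid(np.interp(nodes, t, beat.voltage), nodes))
    sti = float(np.trapezoid(np.interp(nodes, t, beat.speed), nodes))
    return vti, sti


def dyssynchrony_index(vti, sti, k_norm: float, m_norm: float,
                       norm_vti: float = NORM_VTI,
                       norm_sti: float = NORM_STI):
    """Normalized perpendicular distance of (VTI, STI) to the control line."""
    vti_n = np.asarray(vti, dtype=float) / norm_vti
    sti_n = np.asarray(sti, dtype=float) / norm_sti
    out = np.abs(k_norm + m_norm * vti_n - sti_n) / np.sqrt(1.0 + m_norm**2)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Control-line model
# ---------------------------------------------------------------------------

class ControlLine:
    """OLS model of normalized STI on normalized VTI in a control population.

    Parameters
    ----------
    vti, sti : array_like
        Control measurements in raw units (mV·ms and mV).
    norm_vti, norm_sti : float
        Nondimensionalization constants (defaults 100 mV·ms and 10,000 mV).

    ``fit()`` returns a :class:`ControlLineResults` carrying the normalized
    intercept/slope, their standard errors, r², and the index computation.
    """

    def __init__(self, vti, sti, norm_vti: float = NORM_VTI,
                 norm_sti: float = NORM_STI):
        vti = np.asarray(vti, dtype=float)
        sti = np.asarray(sti, dtype=float)
        if vti.shape != sti.shape or vti.ndim != 1:
            raise ParameterError("vti and sti must be equal-length 1-D arrays")
        if vti.size < 3:
            raise ParameterError("need at least 3 control measurements")
        if np.ptp(vti) == 0:
            raise ParameterError("degenerate control data: zero VTI variance")
        self.vti = vti
        self.sti = sti
        self.norm_vti = norm_vti
        self.norm_sti = norm_sti

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, vti_col: str = "vti",
                       sti_col: str = "sti", **kwargs) -> "ControlLine":
        return cls(df[vti_col].to_numpy(), df[sti_col].to_numpy(), **kwargs)

    @classmethod
    def from_measurements(cls, measurements, **kwargs) -> "ControlLine":
        return cls([m.vti for m in measurements],
                   [m.sti for m in measurements], **kwargs)

    def fit(self) -> "ControlLineResults":
        x = self.vti / self.norm_vti
        y = self.sti / self.norm_sti
        res = sm.OLS(y, sm.add_constant(x)).fit()
        return ControlLineResults(
            k_norm=float(res.params[0]),
            m_norm=float(res.params[1]),
            k_se=float(res.bse[0]),
            m_se=float(res.bse[1]),
            r2=float(res.rsquared),
            n=int(self.vti.size),
            norm_vti=self.norm_vti,
            norm_sti=self.norm_sti,
            _sm_results=res,
            _vti=self.vti,
        )


@dataclass
class ControlLineResults:
    """Fitted control line in normalized coordinates.

    ``slope_raw`` converts the normalized slope back to the raw STI/VTI slope
    in ms⁻¹: slope_raw = m_norm × (norm_sti / norm_vti).
    """

    k_norm: float
    m_norm: float
    k_se: float
    m_se: float
    r2: float
    n: int
    norm_vti: float = NORM_VTI
    norm_sti: float = NORM_STI
    _sm_results: object | None = field(default=None, repr=False, compare=False)
    _vti: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.k_norm, self.m_norm])

    @property
    def bse(self) -> np.ndarray:
        return np.array([self.k_se, self.m_se])

    @property
    def slope_raw(self) -> float:
        """Raw-unit slope of STI on VTI, ms⁻¹ (the inverse tissue characteristic time)."""
        return self.m_norm * (self.norm_sti / self.norm_vti)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        if self._sm_results is None:
            raise ParameterError("confidence intervals need the fitted model "
                                 "(not available on a model loaded from JSON)")
        return np.asarray(self._sm_results.conf_int(alpha))

    def confidence_band(self, vti_grid, alpha: float = 0.05):
        """OLS mean-response confidence band of normalized STI on a VTI grid (raw units)."""
        if self._sm_results is None:
            raise ParameterError("confidence band needs the fitted model")
        x = np.asarray(vti_grid, dtype=float) / self.norm_vti
        pred = self._sm_results.get_prediction(sm.add_constant(x))
        lo, hi = pred.conf_int(alpha=alpha).T
        return lo * self.norm_sti, hi * self.norm_sti

    def predict_sti(self, vti):
        """Expected STI (raw units) on the control line at the given VTI."""
        vti_n = np.asarray(vti, dtype=float) / self.norm_vti
        return (self.k_norm + self.m_norm * vti_n) * self.norm_sti

    def index(self, vti, sti):
        """Dyssynchrony index of one or more (VTI, STI) points."""
        return dyssynchrony_index(vti, sti, self.k_norm, self.m_norm,
                                  self.norm_vti, self.norm_sti)

    def score(self, df: pd.DataFrame, vti_col: str = "vti",
              sti_col: str = "sti") -> pd.DataFrame:
        """Return a copy of ``df`` with an ``index`` column appended."""
        out = df.copy()
        out["index"] = self.index(out[vti_col].to_numpy(), out[sti_col].to_numpy())
        return out

    def summary(self) -> str:
        lines = [
            "Control line (normalized STI on normalized VTI, OLS)",
            "----------------------------------------------------",
            f"n controls          {self.n:>10d}",
            f"intercept k_norm    {self.k_norm:>10.4f}  (se {self.k_se:.4f})",
            f"slope m_norm        {self.m_norm:>10.4f}  (se {self.m_se:.4f})",
            f"slope raw [1/ms]    {self.slope_raw:>10.2f}",
            f"r^2                 {self.r2:>10.4f}",
            f"norms: VTI/{self.norm_vti:g} mV·ms, STI/{self.norm_sti:g} mV",
        ]
        return "\n".join(lines)

    def plot(self, vti=None, sti=None, ax=None):
        """Scatter + fitted line + 95% confidence band (matplotlib required)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pts_v = self._vti if vti is None else np.asarray(vti, dtype=float)
        grid = np.linspace(0, max(1.0, pts_v.max() * 1.1), 200) if pts_v is not None \
            else np.linspace(0, 2 * self.norm_vti, 200)
        ax.plot(grid, self.predict_sti(grid), "b-", label="control line")
        if self._sm_results is not None:
            lo, hi = self.confidence_band(grid)
            ax.plot(grid, lo, "b:", grid, hi, "b:")
        if vti is not None and sti is not None:
            ax.scatter(vti, sti, s=12, c="k")
        ax.set_xlabel("VTI (mV·ms)")
        ax.set_ylabel("STI (mV)")
        return ax

    def to_json(self, path: str | Path) -> None:
        save_json({
            "k_norm": self.k_norm, "m_norm": self.m_norm,
            "k_se": self.k_se, "m_se": self.m_se,
            "r2": self.r2, "n": self.n,
            "norm_vti": self.norm_vti, "norm_sti": self.norm_sti,
        }, path)

    @classmethod
    def from_json(cls, path: str | Path) -> "ControlLineResults":
        d = load_json(path)
        return cls(**{k: d[k] for k in
                      ("k_norm", "m_norm", "k_se", "m_se", "r2", "n",
                       "norm_vti", "norm_sti")})


# ---------------------------------------------------------------------------
# Youden-optimal cutoff
# ---------------------------------------------------------------------------

class YoudenCutoff:
    """Cutoff selection on the dyssynchrony index via the Youden index.

    ``labels`` mark the electrically dyssynchronous class (1 = LBBB/PM-like).
    ``fit()`` sweeps every midpoint between sorted unique index values,
    classifies ``index >= cutoff`` as positive, and returns the plateau of
    cutoffs maximizing sensitivity + specificity − 1.  A logistic regression
    of label on index is fitted alongside for probability reporting.
    """

    def __init__(self, index, labels):
        index = np.asarray(index, dtype=float)
        labels = np.asarray(labels).astype(int)
        if index.shape != labels.shape or index.ndim != 1:
            raise ParameterError("index and labels must be equal-length 1-D arrays")
        if set(np.unique(labels)) != {0, 1}:
            raise ParameterError("both classes must be present in labels")
        self.index = index
        self.labels = labels

    def fit(self) -> "CutoffResults":
        idx, lab = self.index, self.labels
        u = np.unique(idx)
        if u.size < 2:
            raise ParameterError("all index values identical; no cutoff exists")
        mids = (u[:-1] + u[1:]) / 2
        n_pos = lab.sum()
        n_neg = lab.size - n_pos
        # Youden at each midpoint cutoff c: positive call is index >= c
        sens = np.array([(lab[idx >= c].sum()) / n_pos for c in mids])
        spec = np.array([((1 - lab)[idx < c].sum()) / n_neg for c in mids])
        youden = sens + spec - 1
        best = youden.max()
        winners = np.nonzero(np.isclose(youden, best, atol=1e-12))[0]
        # first contiguous block of maximal midpoints -> plateau (u[i], u[j+1]]
        block_end = winners[0]
        for w in winners[1:]:
            if w == block_end + 1:
                block_end = w
            else:
                break
        lo = float(u[winners[0]])
        hi = float(u[block_end + 1])
        mean = (lo + hi) / 2

        logit_params, converged = self._fit_logistic()
        call = idx >= mean
        sens_m = float(lab[call].sum() / n_pos)
        spec_m = float((1 - lab)[~call].sum() / n_neg)
        return CutoffResults(
            cutoff_lo=lo, cutoff_hi=hi, cutoff_mean=mean,
            max_youden=float(best),
            sensitivity=sens_m, specificity=spec_m,
            logit_intercept=float(logit_params[0]),
            logit_slope=float(logit_params[1]),
            logit_converged=converged,
            n_positive=int(n_pos), n_negative=int(n_neg),
        )

    def _fit_logistic(self) -> tuple[np.ndarray, bool]:
        import warnings

        X = sm.add_constant(self.index)
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(self.labels, X).fit(disp=0, maxiter=200)
            params = np.asarray(res.params)
            # diverging coefficients signal (quasi-)separation
            if (np.all(np.isfinite(params)) and np.all(np.abs(params) < 1e3)
                    and res.mle_retvals.get("converged", False)):
                return params, True
        except Exception:
            pass
        # perfect separation (common on clean synthetic cohorts): fall back to
        # a weakly ridge-regularized fit for the probability curve
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1e4, solver="lbfgs", max_iter=5000)
        lr.fit(self.index[:, None], self.labels)
        return np.array([lr.intercept_[0], lr.coef_[0][0]]), False


@dataclass
class CutoffResults:
    """Maximal-Youden cutoff plateau and the accompanying logistic fit."""

    cutoff_lo: float
    cutoff_hi: float
    cutoff_mean: float
    max_youden: float
    sensitivity: float
    specificity: float
    logit_intercept: float
    logit_slope: float
    logit_converged: bool
    n_positive: int
    n_negative: int

    def predict_proba(self, index):
        """P(dyssynchronous | index) from the logistic model."""
        z = self.logit_intercept + self.logit_slope * np.asarray(index, dtype=float)
        return 1.0 / (1.0 + np.exp(-z))

    def summary(self) -> str:
        lines = [
            "Youden-optimal dyssynchrony-index cutoff",
            "----------------------------------------",
            f"n (dyssynchronous / other)  {self.n_positive} / {self.n_negative}",
            f"cutoff range                [{self.cutoff_lo:.4f}, {self.cutoff_hi:.4f}]",
            f"cutoff (mean of range)      {self.cutoff_mean:.4f}",
            f"max Youden index            {self.max_youden:.4f}",
            f"sens/spec at mean cutoff    {self.sensitivity:.3f} / {self.specificity:.3f}",
            f"logistic: intercept {self.logit_intercept:.3f}, "
            f"slope {self.logit_slope:.3f}"
            + ("" if self.logit_converged else "  (ridge fallback: separation)"),
        ]
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        save_json({k: getattr(self, k) for k in (
            "cutoff_lo", "cutoff_hi", "cutoff_mean", "max_youden",
            "sensitivity", "specificity", "logit_intercept", "logit_slope",
            "logit_converged", "n_positive", "n_negative")}, path)


# ---------------------------------------------------------------------------
# TPS-SD (echocardiographic mechanical dyssynchrony)
# ---------------------------------------------------------------------------

@dataclass
class TpsSdResult:
    sd_ms: float
    peak_times_ms: np.ndarray
    segment_ids: tuple[str, ...]


def tps_sd(table: StrainTable, flat_tol: float = 1e-9) -> TpsSdResult:
    """Standard deviation of the time to minimum systolic strain over 18 segments.

    Per segment the time of the minimum (peak negative) strain is located on
    the common time axis; the statistic is the sample (n−1) standard deviation
    of those 18 times, in ms.  A flat strain curve has no peak and raises,
    naming the offending segment.
    """
    times = np.empty(18)
    for j, (sid, curve) in enumerate(zip(table.segment_ids, table.curves)):
        if np.ptp(curve) <= flat_tol:
            raise ParameterError(f"flat strain curve in segment {sid!r}")
        times[j] = table.time_ms[int(np.argmin(curve))]
    return TpsSdResult(
        sd_ms=float(np.std(times, ddof=1)),
        peak_times_ms=times,
        segment_ids=tuple(table.segment_ids),
    )
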