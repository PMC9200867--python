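"""Vectorcardiogram reconstruction and instantaneous voltage/speed.

The orthogonal X/Y/Z leads are reconstructed from the 8 independent standard
leads (I, II, V1–V6) with the Kors regression matrix; the augmented limb leads
are linear combinations of I and II and carry no extra information.

Two derived series drive the whole analysis:

* ``voltage(t) = sqrt(X² + Y² + Z²)`` — spatial magnitude of the cardiac
  dipole, in mV;
* ``speed(t) = |d(X,Y,Z)/dt|`` — magnitude of the dipole's velocity, in mV/s
  (derivatives by second-order central differences, one-sided at the ends).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError
from .io import INDEPENDENT_LEADS, STANDARD_LEADS, ECGRecord

# Kors regression matrix (Kors et al., Eur Heart J 1990): rows X, Y, Z;
# columns I, II, V1, V2, V3, V4, V5, V6. Coefficients are dimensionless.
KORS_MATRIX = np.array([
    [0.38, -0.07, -0.13, 0.05, -0.01, 0.14, 0.06, 0.54],
    [-0.07, 0.93, 0.06, -0.02, -0.05, 0.06, -0.17, 0.13],
    [0.11, -0.23, -0.43, -0.06, -0.14, -0.20, -0.11, 0.31],
])

_INDEP_IDX = [STANDARD_LEADS.index(name) for name in INDEPENDENT_LEADS]


@dataclass
class VCGSignal:
    """Orthogonal X/Y/Z series (mV) with derived voltage (mV) and speed (mV/s)."""

    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray
    voltage: np.ndarray
    speed: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        n = {len(s) for s in (self.X, self.Y, self.Z, self.voltage, self.speed)}
        if len(n) != 1:
            raise ParameterError("all VCG series must share one length")

    @property
    def xyz(self) -> np.ndarray:
        """Stacked (3, n) view of the orthogonal leads."""
        return np.vstack([self.X, self.Y, self.Z])


def compute_voltage(X: np.ndarray, Y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Element-wise Euclidean norm of the dipole vector, mV."""
    X, Y, Z = (np.asarray(a, dtype=float) for a in (X, Y, Z))
    if not (X.shape == Y.shape == Z.shape):
        raise ParameterError("X, Y, Z must have equal lengths")
    return np.sqrt(X**2 + Y**2 + Z**2)


def compute_speed(X: np.ndarray, Y: np.ndarray, Z: np.ndarray,
                  sampling_rate: float) -> np.ndarray:
    """Element-wise norm of the dipole's time derivative, in mV/s.

    Uses second-order central differences in the interior and second-order
    one-sided stencils at the boundaries, so the output length equals the
    input length.
    """
    X, Y, Z = (np.asarray(a, dtype=float) for a in (X, Y, Z))
    if X.size < 3:
        raise ParameterError("need at least 3 samples to differentiate")
    if not (X.shape == Y.shape == Z.shape):
        raise ParameterError("X, Y, Z must have equal lengths")
    # np.gradient is per-sample; multiply by fs (samples/s) to get mV/s
    dx = np.gradient(X, edge_order=2) * sampling_rate
    dy = np.gradient(Y, edge_order=2) * sampling_rate
    dz = np.gradient(Z, edge_order=2) * sampling_rate
    return np.sqrt(dx**2 + dy**2 + dz**2)


def kors_transform(record: ECGRecord) -> VCGSignal:
    """Reconstruct the VCG from a 12-lead record via the Kors matrix."""
    xyz = KORS_MATRIX @ record.samples[_INDEP_IDX]
    X, Y, Z = xyz
    return VCGSignal(
        X=X, Y=Y, Z=Z,
        voltage=compute_voltage(X, Y, Z),
        speed=compute_speed(X, Y, Z, record.sampling_rate),
        sampling_rate=record.sampling_rate,
    )
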