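"""Reading and writing ECG recordings and strain tables.

Two input formats are supported for 12-lead ECGs: WFDB header/signal pairs
(format 16, the format used by the PhysioNet PTB diagnostic ECG database)
and comma-separated text with one column per lead, as exported by digital
electrocardiographs sampling at 1000 Hz.

Internal conventions, enforced at read time:

* lead order is canonical: I, II, III, aVR, aVL, aVF, V1–V6;
* samples are in millivolts;
* the sampling rate is 1000 Hz (other rates are resampled on read);
* only the first ``segment_seconds`` (default 10 s) of longer records are kept.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .exceptions import LeadMissingError, ParameterError, ParseError

logger = logging.getLogger(__name__)

#: Canonical order of the 12 standard leads; every downstream matrix assumes it.
STANDARD_LEADS: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

#: The 8 linearly independent leads used by the Kors transform.
INDEPENDENT_LEADS: tuple[str, ...] = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

_LEAD_ALIASES = {name.lower(): name for name in STANDARD_LEADS}

#: Conduction-class labels used throughout the package.
KNOWN_LABELS = (
    "NC", "IRBBB", "LAFB", "LPFB", "RBBB", "RBBB+LAFB",
    "ILBBB", "LBBB", "PM/CRT", "control",
)

#: Target sampling rate of the analysis pipeline, Hz.
TARGET_FS = 1000.0

#: 18-segment left-ventricular model: 6 basal, 6 mid, 6 apical walls.
SEGMENT_18 = tuple(
    f"{level}_{wall}"
    for level in ("basal", "mid", "apical")
    for wall in ("anterior", "anteroseptal", "inferoseptal",
                 "inferior", "inferolateral", "anterolateral")
)


@dataclass
class ECGRecord:
    """A digitized 12-lead ECG in canonical lead order.

    Parameters
    ----------
    patient_id : str
        Identifier carried through to the results table.
    samples : ndarray, shape (12, n)
        Per-lead series in millivolts, canonical lead order.
    sampling_rate : float
        Samples per second; the analysis pipeline assumes 1000 Hz.
    label : str or None
        Optional conduction-class label (``NC``, ``RBBB``, ``LBBB`` ...).
    processing_log : list of str
        Human-readable record of the preprocessing steps applied so far.
    """

    patient_id: str
    samples: np.ndarray
    sampling_rate: float = TARGET_FS
    label: str | None = None
    lead_names: tuple[str, ...] = STANDARD_LEADS
    processing_log: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != 12:
            raise ParameterError(
                f"expected 12 leads, got array of shape {self.samples.shape}"
            )
        if tuple(self.lead_names) != STANDARD_LEADS:
            raise ParameterError("lead_names must be the canonical 12-lead order")
        if not self.sampling_rate > 0:
            raise ParameterError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("sample values must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sampling_rate

    def lead(self, name: str) -> np.ndarray:
        """Return one lead by standard name (case-insensitive)."""
        key = name.lower()
        if key not in _LEAD_ALIASES:
            raise ParameterError(f"unknown lead name {name!r}")
        return self.samples[STANDARD_LEADS.index(_LEAD_ALIASES[key])]

    def copy_with(self, samples: np.ndarray, log_entry: str | None = None) -> "ECGRecord":
        log = list(self.processing_log)
        if log_entry:
            log.append(log_entry)
        return ECGRecord(
            patient_id=self.patient_id,
            samples=samples,
            sampling_rate=self.sampling_rate,
            label=self.label,
            processing_log=log,
        )


@dataclass
class StrainTable:
    """Per-segment longitudinal strain curves on a common time axis.

    ``time_ms`` starts at QRS onset; ``curves`` holds one strain series (%)
    per left-ventricular segment, 18 segments in the standard basal/mid/apical
    6-wall layout.
    """

    segment_ids: tuple[str, ...]
    time_ms: np.ndarray
    curves: np.ndarray  # shape (18, n), percent strain

    def __post_init__(self):
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.curves = np.asarray(self.curves, dtype=float)
        if len(self.segment_ids) != 18 or self.curves.shape[0] != 18:
            raise ParameterError("a strain table must have exactly 18 segments")
        if self.curves.shape[1] != self.time_ms.size:
            raise ParameterError("curves and time axis disagree in length")
        if self.time_ms.size < 2 or np.any(np.diff(self.time_ms) <= 0):
            raise ParameterError("time axis must be strictly increasing")


# ---------------------------------------------------------------------------
# WFDB (header + format-16 signal file)
# ---------------------------------------------------------------------------

_GAIN_RE = re.compile(r"^(?P<gain>-?[\d.]+)(?:\((?P<baseline>-?\d+)\))?(?:/(?P<units>\S+))?$")


def _parse_header(hea_path: Path):
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise ParseError(f"empty WFDB header: {hea_path}")
    rec = lines[0].split()
    if len(rec) < 3:
        raise ParseError(f"malformed WFDB record line: {lines[0]!r}")
    name = rec[0].split("/")[0]
    n_sig = int(rec[1])
    fs = float(rec[2].split("/")[0])
    n_samp = int(rec[3]) if len(rec) > 3 else None
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        f = ln.split()
        if len(f) < 2:
            raise ParseError(f"malformed WFDB signal line: {ln!r}")
        fname = f[0]
        fmt = f[1].split("x")[0].split(":")[0].split("+")[0]
        gain, baseline = 200.0, None
        if len(f) > 2:
            m = _GAIN_RE.match(f[2])
            if not m:
                raise ParseError(f"cannot parse gain spec {f[2]!r}")
            gain = float(m.group("gain")) or 200.0
            if m.group("baseline") is not None:
                baseline = int(m.group("baseline"))
        adc_zero = int(f[4]) if len(f) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        desc = f[8] if len(f) > 8 else f"ch{len(signals)}"
        signals.append({"file": fname, "fmt": fmt, "gain": gain,
                        "baseline": baseline, "desc": desc})
    return name, n_sig, fs, n_samp, signals


def read_wfdb(path: str | Path, segment_seconds: float = 10.0,
              patient_id: str | None = None, label: str | None = None) -> ECGRecord:
    """Read a WFDB record (format 16) and return the first ``segment_seconds``.

    ``path`` may point at the ``.hea`` file or be the extensionless record
    name.  Extra channels beyond the 12 standard leads (e.g. the Frank vx/vy/vz
    leads of PTB records) are dropped; a missing standard lead raises
    :class:`LeadMissingError`.  Records sampled at a rate other than 1000 Hz
    are resampled.
    """
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise ParseError(f"WFDB header not found: {hea}")
    name, n_sig, fs, n_samp, signals = _parse_header(hea)

    fmts = {s["fmt"] for s in signals}
    if fmts != {"16"}:
        raise ParseError(f"unsupported WFDB signal format(s) {sorted(fmts)}; "
                         "only format 16 is supported")
    dat_files = [s["file"] for s in signals]
    if len(set(dat_files)) != 1:
        raise ParseError("multi-file WFDB records are not supported")
    dat = hea.parent / dat_files[0]
    try:
        raw = np.fromfile(dat, dtype="<i2")
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise ParseError(f"cannot read signal file {dat}: {exc}") from exc
    if raw.size % n_sig:
        raw = raw[: raw.size - raw.size % n_sig]
    adc = raw.reshape(-1, n_sig).T.astype(float)
    if n_samp is not None:
        adc = adc[:, :n_samp]

    by_name: dict[str, np.ndarray] = {}
    for s, chan in zip(signals, adc):
        key = s["desc"].lower()
        if key in _LEAD_ALIASES:
            by_name[_LEAD_ALIASES[key]] = (chan - s["baseline"]) / s["gain"]
    for lead_name in STANDARD_LEADS:
        if lead_name not in by_name:
            raise LeadMissingError(lead_name, str(hea))
    samples = np.vstack([by_name[ln] for ln in STANDARD_LEADS])

    if fs != TARGET_FS:
        up, down = (np.array([TARGET_FS, fs]) /
                    np.gcd(int(round(TARGET_FS)), int(round(fs)))).astype(int)
        samples = resample_poly(samples, up, down, axis=1)
        fs = TARGET_FS

    want = int(round(segment_seconds * fs))
    if samples.shape[1] < want:
        msg = (f"record {name}: only {samples.shape[1] / fs:.2f} s available, "
               f"{segment_seconds:.2f} s requested")
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    samples = samples[:, :want]

    return ECGRecord(
        patient_id=patient_id or name,
        samples=samples,
        sampling_rate=fs,
        label=label,
        processing_log=[f"read_wfdb({hea.name})"],
    )


def write_wfdb(record: ECGRecord, path: str | Path, gain: float = 2000.0) -> None:
    """Write a record as a WFDB header + format-16 signal pair.

    Mainly used by the simulator and by round-trip tests; amplitude resolution
    is 1/``gain`` mV (0.5 µV at the default gain).
    """
    path = Path(path)
    stem = path.with_suffix("")
    adc = np.clip(np.round(record.samples * gain), -32768, 32767).astype("<i2")
    n = record.n_samples
    lines = [f"{stem.name} 12 {record.sampling_rate:g} {n}"]
    for i, lead_name in enumerate(STANDARD_LEADS):
        first = int(adc[i, 0]) if n else 0
        lines.append(
            f"{stem.name}.dat 16 {gain:g}(0)/mV 16 0 {first} 0 0 {lead_name.lower()}"
        )
    stem.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    adc.T.tofile(stem.with_suffix(".dat"))


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

@dataclass
class CsvDialect:
    """How to interpret a comma-separated ECG file.

    ``scale`` multiplies raw values into millivolts (use 0.001 for µV columns);
    ``sampling_rate`` is the acquisition rate in Hz.
    """

    sampling_rate: float = TARGET_FS
    scale: float = 1.0
    delimiter: str = ","


def read_csv(path: str | Path, dialect: CsvDialect | None = None,
             segment_seconds: float = 10.0,
             patient_id: str | None = None, label: str | None = None) -> ECGRecord:
    """Read a comma-separated ECG (header row of lead names, one column per lead)."""
    dialect = dialect or CsvDialect()
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.delimiter)
    cols = {c.strip().lower(): c for c in df.columns}
    missing = [ln for ln in STANDARD_LEADS if ln.lower() not in cols]
    if missing:
        if len(missing) == 12 or len(df.columns) != 12:
            raise ParseError(
                f"{path}: expected 12 lead columns {STANDARD_LEADS}, "
                f"got {tuple(df.columns)}"
            )
        raise LeadMissingError(missing[0], str(path))
    data = df[[cols[ln.lower()] for ln in STANDARD_LEADS]]
    numeric = data.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~data.isna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy())[0][0])
        raise ParseError(f"{path}: non-numeric cell at data row {row}")
    if numeric.isna().to_numpy().any():
        row = int(np.argwhere(numeric.isna().to_numpy())[0][0])
        raise ParseError(f"{path}: missing value at data row {row}")

    samples = numeric.to_numpy().T * dialect.scale
    fs = dialect.sampling_rate
    if fs != TARGET_FS:
        up, down = (np.array([TARGET_FS, fs]) /
                    np.gcd(int(round(TARGET_FS)), int(round(fs)))).astype(int)
        samples = resample_poly(samples, up, down, axis=1)
        fs = TARGET_FS
    want = int(round(segment_seconds * fs))
    if samples.shape[1] < want:
        msg = f"{path.name}: shorter than the requested {segment_seconds:g}-s segment"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    samples = samples[:, :want]
    return ECGRecord(
        patient_id=patient_id or path.stem,
        samples=samples,
        sampling_rate=fs,
        label=label,
        processing_log=[f"read_csv({path.name})"],
    )


def write_csv(record: ECGRecord, path: str | Path) -> None:
    """Write a record as CSV with one millivolt column per standard lead."""
    df = pd.DataFrame(record.samples.T, columns=list(STANDARD_LEADS))
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Strain tables and result tables
# ---------------------------------------------------------------------------

def read_strain_csv(path: str | Path) -> StrainTable:
    """Read an exported time–strain table: a time column (ms) + 18 segment columns."""
    path = Path(path)
    df = pd.read_csv(path)
    time_cols = [c for c in df.columns if c.strip().lower() in ("time", "time_ms", "t", "ms")]
    if not time_cols:
        raise ParseError(f"{path}: no time column (expected 'time_ms')")
    seg_cols = [c for c in df.columns if c not in time_cols]
    if len(seg_cols) != 18:
        raise ParseError(f"{path}: expected 18 segment columns, got {len(seg_cols)}")
    return StrainTable(
        segment_ids=tuple(seg_cols),
        time_ms=df[time_cols[0]].to_numpy(dtype=float),
        curves=df[seg_cols].to_numpy(dtype=float).T,
    )


def write_strain_csv(table: StrainTable, path: str | Path) -> None:
    df = pd.DataFrame({"time_ms": table.time_ms})
    for sid, curve in zip(table.segment_ids, table.curves):
        df[sid] = curve
    df.to_csv(path, index=False)


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
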