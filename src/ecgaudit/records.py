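"""Canonical 12-lead ECG data model, readers/writers, resampling and screening.

All signals are stored as a ``(12, n_samples)`` float array in millivolts,
with leads in the fixed canonical order ``I, II, III, aVR, aVL, aVF,
V1 ... V6``.  Every other module in the package assumes this convention.
"""

from __future__ import annotations

import csv
import io as _io
import logging
import math
import struct
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import resample_poly

__all__ = [
    "LEAD_NAMES",
    "ECGRecord",
    "QualityFlag",
    "QualityReport",
    "FormatError",
    "UnitError",
    "read_ecg",
    "write_ecg",
    "resample_record",
    "lead_consistency_check",
    "quality_screen",
]

logger = logging.getLogger(__name__)

#: Canonical 12-lead order assumed by every module.
LEAD_NAMES: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

_LEAD_INDEX = {name.upper(): i for i, name in enumerate(LEAD_NAMES)}

# The four limb-lead identities that hold whenever the 12 leads derive from
# three limb electrode potentials: III = II - I, aVR = -(I+II)/2,
# aVL = I - II/2, aVF = II - I/2.  Each entry maps the derived lead to a
# callable computing its prediction from leads I and II; predictions use the
# exact floating-point expressions the generators use, so records built from
# electrode potentials pass with deviation exactly zero.
_DERIVED_LEAD_IDENTITIES: tuple[tuple[str, str, object], ...] = (
    ("III = II - I", "III", lambda i, ii: ii - i),
    ("aVR = -(I+II)/2", "aVR", lambda i, ii: -(i + ii) / 2.0),
    ("aVL = I - II/2", "aVL", lambda i, ii: i - ii / 2.0),
    ("aVF = II - I/2", "aVF", lambda i, ii: ii - i / 2.0),
)


class FormatError(ValueError):
    """Raised when a file cannot be parsed as a 12-lead ECG."""


class UnitError(ValueError):
    """Raised when the voltage units of a source file cannot be resolved."""


@dataclass
class ECGRecord:
    """A 12-lead ECG: ``signal`` is ``(12, n)`` in mV, canonical lead order."""

    record_id: str
    signal: np.ndarray
    sampling_rate: float
    lead_names: tuple[str, ...] = LEAD_NAMES

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2 or self.signal.shape[0] != 12:
            raise ValueError(
                f"signal must be a (12, n) matrix, got shape {self.signal.shape}"
            )
        if not np.all(np.isfinite(self.signal)):
            # Non-finite samples are representable (quality_screen flags them)
            # but we warn rather than refuse.
            logger.debug("record %s contains non-finite samples", self.record_id)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.lead_names = tuple(self.lead_names)
        if self.lead_names != LEAD_NAMES:
            raise ValueError("lead_names must be the canonical 12-lead order")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def lead(self, name: str) -> np.ndarray:
        """Return one lead's series by name (case-insensitive)."""
        return self.signal[_LEAD_INDEX[name.upper()]]

    def copy(self, **updates) -> "ECGRecord":
        kwargs = dict(
            record_id=self.record_id,
            signal=self.signal.copy(),
            sampling_rate=self.sampling_rate,
        )
        kwargs.update(updates)
        return ECGRecord(**kwargs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ECGRecord):
            return NotImplemented
        return (
            self.record_id == other.record_id
            and self.sampling_rate == other.sampling_rate
            and self.signal.shape == other.signal.shape
            and np.array_equal(self.signal, other.signal)
        )


@dataclass(frozen=True)
class QualityFlag:
    kind: str  # flat_lead | missing_samples | clipping | out_of_range
    lead_indices: tuple[int, ...]


@dataclass(frozen=True)
class QualityReport:
    record_id: str
    passed: bool
    flags: tuple[QualityFlag, ...] = ()

    def __post_init__(self) -> None:
        if self.passed != (len(self.flags) == 0):
            raise ValueError("passed must be true iff flags is empty")


@dataclass(frozen=True)
class QualityConfig:
    """Screening thresholds (defaults are declared stand-ins, logged on use)."""

    flat_sd_mv: float = 0.01
    clip_run_length: int = 10
    clip_level_mv: float | None = None  # None -> per-record max |value|
    range_limit_mv: float = 20.0


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _canonicalize(signal: np.ndarray, source_leads: Sequence[str]) -> np.ndarray:
    """Reorder a lead-by-sample matrix into canonical order."""
    upper = [s.strip().upper() for s in source_leads]
    missing = [name for name in LEAD_NAMES if name.upper() not in upper]
    if missing:
        raise FormatError(f"missing leads: {', '.join(missing)}")
    order = [upper.index(name.upper()) for name in LEAD_NAMES]
    return signal[order]


def read_ecg(path: str | Path, format: str | None = None) -> ECGRecord:
    """Read a 12-lead ECG from WFDB, CSV, or the array-container format.

    The format is inferred from the file suffix when not given
    (``.hea`` -> wfdb, ``.csv`` -> csv, ``.ecgz``/``.zip`` -> array container).
    Source lead order may differ from canonical; it is reordered on read.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "wfdb":
        return _read_wfdb(path)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "array":
        return _read_array(path)
    raise ValueError(f"unknown format {fmt!r}; expected wfdb, csv or array")


def write_ecg(record: ECGRecord, path: str | Path, format: str | None = None) -> Path:
    """Write ``record`` so that :func:`read_ecg` round-trips it value-exact."""
    path = Path(path)
    fmt = format or _infer_format(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "wfdb":
        _write_wfdb(record, path)
    elif fmt == "csv":
        _write_csv(record, path)
    elif fmt == "array":
        _write_array(record, path)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected wfdb, csv or array")
    return path


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".hea", ".dat"}:
        return "wfdb"
    if suffix == ".csv":
        return "csv"
    if suffix in {".ecgz", ".zip", ".npz"}:
        return "array"
    raise ValueError(f"cannot infer ECG format from suffix {suffix!r}")


# -- WFDB (text .hea header + little-endian int16 .dat, format 16) ----------
#
# Minimal self-contained implementation of the classic WFDB signal file
# layout: one record = <name>.hea describing 12 format-16 signals stored
# interleaved in <name>.dat with per-signal gain (ADU/mV) and baseline.

_WFDB_GAIN = 1000.0  # ADU per mV on write; read honors the header gain


def _write_wfdb(record: ECGRecord, path: Path) -> None:
    base = path.with_suffix("")
    n = record.n_samples
    adc = np.round(record.signal * _WFDB_GAIN).astype(np.int64)
    if np.any(np.abs(adc) > 32767):
        raise ValueError(
            "signal exceeds int16 range at gain 1000 ADU/mV; rescale before "
            "writing WFDB"
        )
    adc16 = adc.astype("<i2")
    fs = record.sampling_rate
    fs_str = f"{fs:g}"
    lines = [f"{base.name} 12 {fs_str} {n}"]
    dat_name = base.name + ".dat"
    for i, lead in enumerate(record.lead_names):
        first = int(adc16[i, 0]) if n else 0
        lines.append(
            f"{dat_name} 16 {_WFDB_GAIN:g}(0)/mV 16 0 {first} 0 0 {lead}"
        )
    base.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    # sample-interleaved: frame = one sample of each signal
    base.with_suffix(".dat").write_bytes(adc16.T.tobytes())


def _read_wfdb(path: Path) -> ECGRecord:
    base = path.with_suffix("")
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"WFDB header not found: {hea}")
    lines = [
        ln for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    n_sig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else None
    if n_sig != 12:
        raise FormatError(f"expected 12 leads, header declares {n_sig}")
    leads, gains, baselines = [], [], []
    dat_name = None
    for spec in lines[1 : 1 + n_sig]:
        tok = spec.split()
        dat_name = tok[0]
        if not tok[1].startswith("16"):
            raise FormatError(f"unsupported WFDB signal format {tok[1]!r}")
        gain_field = tok[2] if len(tok) > 2 else "200/mV"
        gain_part = gain_field.split("/")[0]
        units = gain_field.split("/")[1] if "/" in gain_field else "mV"
        if units.lower() not in {"mv", "millivolt", "millivolts"}:
            raise UnitError(f"unsupported WFDB units {units!r}; expected mV")
        if "(" in gain_part:
            gain_s, base_s = gain_part.split("(")
            baselines.append(int(base_s.rstrip(")")))
        else:
            gain_s = gain_part
            baselines.append(0)
        gains.append(float(gain_s) if gain_s else 200.0)
        leads.append(tok[-1])
    raw = np.frombuffer(base.parent.joinpath(dat_name).read_bytes(), dtype="<i2")
    frames = raw.reshape(-1, n_sig).T.astype(np.float64)
    if n_samples is not None and frames.shape[1] != n_samples:
        raise FormatError(
            f"dat file holds {frames.shape[1]} samples but header says {n_samples}"
        )
    signal = (frames - np.asarray(baselines)[:, None]) / np.asarray(gains)[:, None]
    return ECGRecord(
        record_id=base.name,
        signal=_canonicalize(signal, leads),
        sampling_rate=fs,
    )


# -- CSV: header `time_s,I,II,...,V6`, one row per sample -------------------

def _write_csv(record: ECGRecord, path: Path) -> None:
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", *record.lead_names])
        t = np.arange(record.n_samples) / record.sampling_rate
        for j in range(record.n_samples):
            writer.writerow(
                [repr(float(t[j]))] + [repr(float(v)) for v in record.signal[:, j]]
            )


def _read_csv(path: Path) -> ECGRecord:
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if not header or header[0].strip().lower() != "time_s":
            raise FormatError("CSV must start with a 'time_s' column")
        leads = header[1:]
        if len(leads) < 12:
            missing = [n for n in LEAD_NAMES
                       if n.upper() not in {s.strip().upper() for s in leads}]
            raise FormatError(f"missing leads: {', '.join(missing)}")
        rows = [row for row in reader if row]
    times = np.array([float(r[0]) for r in rows])
    if len(times) < 2:
        raise FormatError("CSV must contain at least two samples")
    dt = np.diff(times)
    fs = 1.0 / float(np.median(dt))
    # time stamps go through decimal text; snap fs to the nearest simple
    # rational so write->read preserves the rate exactly
    from fractions import Fraction

    snapped = Fraction(fs).limit_denominator(1000)
    if abs(float(snapped) - fs) < 1e-6 * fs:
        fs = float(snapped)
    signal = np.array([[float(v) for v in r[1:]] for r in rows]).T
    return ECGRecord(
        record_id=path.stem,
        signal=_canonicalize(signal, leads),
        sampling_rate=fs,
    )


# -- array container: zip archive with signal/fs/lead_names/record_id ------

def _write_array(record: ECGRecord, path: Path) -> None:
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        buf = _io.BytesIO()
        np.save(buf, record.signal)
        zf.writestr("signal.npy", buf.getvalue())
        zf.writestr("fs", repr(float(record.sampling_rate)))
        zf.writestr("lead_names", "\n".join(record.lead_names))
        zf.writestr("record_id", record.record_id)


def _read_array(path: Path) -> ECGRecord:
    with zipfile.ZipFile(path) as zf:
        names = set(zf.namelist())
        required = {"signal.npy", "fs", "lead_names", "record_id"}
        if not required <= names:
            raise FormatError(
                f"array container missing entries: {sorted(required - names)}"
            )
        signal = np.load(_io.BytesIO(zf.read("signal.npy")))
        fs = float(zf.read("fs").decode())
        leads = zf.read("lead_names").decode().splitlines()
        record_id = zf.read("record_id").decode()
    if signal.shape[0] != 12:
        raise FormatError(f"expected 12 leads, container holds {signal.shape[0]}")
    return ECGRecord(
        record_id=record_id,
        signal=_canonicalize(signal, leads),
        sampling_rate=fs,
    )


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_record(record: ECGRecord, target_rate: float) -> ECGRecord:
    """Resample all leads to ``target_rate`` with polyphase anti-aliasing.

    Output length is ``round(duration_s * target_rate)``.  Upsampling is
    allowed but logged.  The polyphase low-pass cuts at 0.9x the target
    Nyquist when downsampling.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == record.sampling_rate:
        return record.copy()
    if target_rate > record.sampling_rate:
        logger.info(
            "upsampling %s from %g Hz to %g Hz (interpolation only)",
            record.record_id, record.sampling_rate, target_rate,
        )
    frac = _as_fraction(target_rate / record.sampling_rate)
    up, down = frac
    resampled = resample_poly(
        record.signal, up, down, axis=1, cval=0.0, window=("kaiser", 5.0)
    )
    n_target = round(record.duration_s * target_rate)
    if resampled.shape[1] > n_target:
        resampled = resampled[:, :n_target]
    elif resampled.shape[1] < n_target:
        pad = n_target - resampled.shape[1]
        resampled = np.pad(resampled, ((0, 0), (0, pad)), mode="edge")
    return ECGRecord(
        record_id=record.record_id,
        signal=resampled,
        sampling_rate=float(target_rate),
    )


def _as_fraction(ratio: float, max_den: int = 10_000) -> tuple[int, int]:
    from fractions import Fraction

    f = Fraction(ratio).limit_denominator(max_den)
    return f.numerator, f.denominator


# ---------------------------------------------------------------------------
# consistency + quality
# ---------------------------------------------------------------------------

def lead_consistency_check(
    record: ECGRecord, tolerance: float = 1e-6
) -> tuple[bool, dict[str, float]]:
    """Check the four derived-limb-lead identities.

    Returns ``(ok, deviations)`` where ``deviations`` maps each identity to
    its maximum absolute residual in mV.
    """
    deviations: dict[str, float] = {}
    lead_i, lead_ii = record.lead("I"), record.lead("II")
    for name, derived, predict in _DERIVED_LEAD_IDENTITIES:
        residual = record.lead(derived) - predict(lead_i, lead_ii)
        deviations[name] = float(np.max(np.abs(residual))) if record.n_samples else 0.0
    ok = all(d <= tolerance for d in deviations.values())
    return ok, deviations


def quality_screen(
    record: ECGRecord, config: QualityConfig | None = None
) -> QualityReport:
    """Deterministic per-record quality screen.

    Flags: ``flat_lead`` (per-lead SD below threshold), ``missing_samples``
    (any non-finite sample), ``clipping`` (a run of >= ``clip_run_length``
    samples pinned at the rail), ``out_of_range`` (|value| above limit).
    """
    config = config or QualityConfig()
    flags: list[QualityFlag] = []
    sig = record.signal

    finite = np.isfinite(sig)
    missing = np.where(~finite.all(axis=1))[0]
    if missing.size:
        flags.append(QualityFlag("missing_samples", tuple(int(i) for i in missing)))

    safe = np.where(finite, sig, 0.0)
    sds = safe.std(axis=1)
    flat = np.where(sds < config.flat_sd_mv)[0]
    if flat.size:
        flags.append(QualityFlag("flat_lead", tuple(int(i) for i in flat)))

    clipped_leads = []
    for i in range(12):
        lead = safe[i]
        level = config.clip_level_mv
        if level is None:
            level = float(np.max(np.abs(lead))) if np.any(lead) else 0.0
        if level <= 0:
            continue
        at_rail = np.abs(np.abs(lead) - level) < 1e-12
        if _longest_run(at_rail) >= config.clip_run_length:
            clipped_leads.append(i)
    if clipped_leads:
        flags.append(QualityFlag("clipping", tuple(clipped_leads)))

    out = np.where((np.abs(safe) > config.range_limit_mv).any(axis=1))[0]
    if out.size:
        flags.append(QualityFlag("out_of_range", tuple(int(i) for i in out)))

    return QualityReport(
        record_id=record.record_id, passed=not flags, flags=tuple(flags)
    )


def _longest_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return int(np.max(edges[1::2] - edges[0::2]))
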