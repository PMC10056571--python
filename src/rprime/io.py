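"""Reading and writing ECG traces and per-patient feature tables.

All r'-wave geometry in this package is defined on the *paper-mm* frame: the
coordinate system of a standard printed ECG at 25 mm/s paper speed and
10 mm/mV gain, where 1 mm horizontal = 40 ms and 1 mm vertical = 0.1 mV.
Angles measured on printed traces with a caliper only make sense in that
frame, so every record carries an explicit :class:`Calibration` and geometry
code converts through :func:`to_paper_mm`.

Voltages are always stored internally in millivolts; time in seconds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Calibration",
    "Lead",
    "ICLevel",
    "LeadPlacement",
    "ECGRecord",
    "read_record",
    "write_record",
    "to_paper_mm",
    "from_paper_mm",
    "read_features",
    "write_features",
    "FEATURE_COLUMNS",
]

MIN_SAMPLING_RATE_HZ = 250.0
"""Records sampled below this rate are rejected: slope estimation on an
r'-wave limb needs roughly five samples, which a slower trace cannot supply."""


@dataclass(frozen=True)
class Calibration:
    """Printed-paper calibration of an ECG trace.

    Parameters
    ----------
    paper_speed : float
        Horizontal paper speed in mm per second (standard 25).
    gain : float
        Vertical gain in mm per mV (standard 10, i.e. 1 mV/cm).
    """

    paper_speed: float = 25.0
    gain: float = 10.0

    def __post_init__(self) -> None:
        if self.paper_speed <= 0 or self.gain <= 0:
            raise ValueError("paper_speed and gain must be positive")

    @property
    def ms_per_mm(self) -> float:
        """Milliseconds represented by one horizontal mm (40 at defaults)."""
        return 1000.0 / self.paper_speed

    @property
    def mv_per_mm(self) -> float:
        """Millivolts represented by one vertical mm (0.1 at defaults)."""
        return 1.0 / self.gain


class Lead(str, Enum):
    V1 = "V1"
    V2 = "V2"


class ICLevel(str, Enum):
    """Intercostal space of the electrode: high placements (III, II) increase
    r'-wave detectability over the conventional fourth space."""

    II = "II"
    III = "III"
    IV = "IV"


@dataclass(frozen=True)
class LeadPlacement:
    """A right-precordial lead (V1 or V2) at a given intercostal level."""

    lead: Lead
    ic_level: ICLevel

    def __str__(self) -> str:  # e.g. "V1-IV"
        return f"{self.lead.value}-{self.ic_level.value}"

    @classmethod
    def parse(cls, text: str) -> "LeadPlacement":
        """Parse strings such as ``"V1-IV"``, ``"v2_ii"`` or ``"V1 III"``."""
        token = text.strip().upper().replace("_", "-").replace(" ", "-")
        parts = [p for p in token.split("-") if p]
        if len(parts) != 2:
            raise ValueError(f"cannot parse lead placement from {text!r}")
        return cls(Lead(parts[0]), ICLevel(parts[1]))


@dataclass
class ECGRecord:
    """A calibrated multi-channel ECG trace.

    ``channels`` pairs each :class:`LeadPlacement` with its voltage series in
    mV. All channels share ``sampling_rate`` and length.
    """

    sampling_rate: float
    channels: list[tuple[LeadPlacement, np.ndarray]]
    calibration: Calibration = field(default_factory=Calibration)
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.sampling_rate < MIN_SAMPLING_RATE_HZ:
            raise ValueError(
                f"sampling rate {self.sampling_rate:g} Hz below the "
                f"{MIN_SAMPLING_RATE_HZ:g} Hz floor required for slope estimation"
            )
        if not self.channels:
            raise ValueError("record has no channels")
        lengths = {len(sig) for _, sig in self.channels}
        if len(lengths) != 1:
            raise ValueError("all channels must have equal length")
        self.channels = [
            (pl, np.asarray(sig, dtype=float)) for pl, sig in self.channels
        ]
        for pl, sig in self.channels:
            if not np.all(np.isfinite(sig)):
                raise ValueError(f"channel {pl} contains non-finite voltages")

    @property
    def n_samples(self) -> int:
        return len(self.channels[0][1])

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.n_samples) / self.sampling_rate


def _detect_time_unit(t: np.ndarray) -> float:
    """Return the factor converting the time column to seconds.

    Median step below 0.1 is interpreted as seconds (≥10 Hz would be absurd
    for an ECG in ms), otherwise milliseconds.
    """
    step = float(np.median(np.diff(t)))
    return 1.0 if step < 0.1 else 1e-3


def _uniform_rate(t_s: np.ndarray) -> float:
    steps = np.diff(t_s)
    if len(steps) == 0 or np.any(steps <= 0):
        raise ValueError("non-uniform sampling: time column not strictly increasing")
    mean_step = float(np.mean(steps))
    if np.max(np.abs(steps - mean_step)) > 1e-6 + 1e-4 * mean_step:
        raise ValueError("non-uniform sampling: irregular time steps")
    return 1.0 / mean_step


def read_record(
    path: str | Path,
    format: str = "csv",
    lead_map: Mapping[str, LeadPlacement | str] | None = None,
    calibration: Calibration | None = None,
    patient_id: str | None = None,
) -> ECGRecord:
    """Read an ECG trace from disk.

    Parameters
    ----------
    path : str or Path
        CSV file (time column plus one voltage column per lead, in mV) or a
        WFDB record name (header path without extension).
    format : {"csv", "wfdb"}
        ``"wfdb"`` requires the optional :mod:`wfdb` package.
    lead_map : mapping, optional
        Maps channel/column names to :class:`LeadPlacement` (or parseable
        strings such as ``"V1-IV"``). Unmapped channels are skipped with a
        warning. When omitted, channel names are parsed directly.
    """
    path = Path(path)
    calibration = calibration or Calibration()
    if format == "csv":
        if not path.exists():
            raise FileNotFoundError(path)
        frame = pd.read_csv(path)
        if frame.shape[1] < 2:
            raise ValueError("CSV must have a time column and at least one lead")
        tcol = frame.columns[0]
        t = frame[tcol].to_numpy(dtype=float)
        t_s = t * _detect_time_unit(t)
        fs = _uniform_rate(t_s)
        names = list(frame.columns[1:])
        signals = {name: frame[name].to_numpy(dtype=float) for name in names}
    elif format == "wfdb":
        try:
            import wfdb  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "reading WFDB records requires the optional 'wfdb' package "
                "(pip install rprime[wfdb]); CSV input needs no extras"
            ) from exc
        rec = wfdb.rdrecord(str(path.with_suffix("")))  # pragma: no cover
        fs = float(rec.fs)  # pragma: no cover
        names = list(rec.sig_name)  # pragma: no cover
        signals = {  # pragma: no cover
            name: rec.p_signal[:, i].astype(float) for i, name in enumerate(names)
        }
    else:
        raise ValueError(f"unknown format {format!r}")

    channels: list[tuple[LeadPlacement, np.ndarray]] = []
    for name in names:
        placement: LeadPlacement | None = None
        if lead_map is not None and name in lead_map:
            value = lead_map[name]
            placement = value if isinstance(value, LeadPlacement) else LeadPlacement.parse(value)
        elif lead_map is None:
            try:
                placement = LeadPlacement.parse(name)
            except ValueError:
                placement = None
        if placement is None:
            warnings.warn(f"channel {name!r} not in lead map; skipped", stacklevel=2)
            continue
        channels.append((placement, signals[name]))
    if not channels:
        raise ValueError("no channels could be mapped to lead placements")
    return ECGRecord(
        sampling_rate=fs,
        channels=channels,
        calibration=calibration,
        patient_id=patient_id if patient_id is not None else path.stem,
    )


def write_record(record: ECGRecord, path: str | Path) -> None:
    """Write a record as CSV (time in seconds plus one column per placement)."""
    data = {"time_s": record.time}
    for placement, sig in record.channels:
        data[str(placement)] = sig
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def to_paper_mm(
    record: ECGRecord, channel: int
) -> tuple[np.ndarray, np.ndarray]:
    """Convert one channel to paper-mm coordinates.

    Returns ``(x_mm, y_mm)`` where ``x_mm = t_ms / ms_per_mm`` and
    ``y_mm = v_mV / mV_per_mm``; with default calibration 1 mm is 40 ms
    horizontally and 0.1 mV vertically.
    """
    _, sig = record.channels[channel]
    cal = record.calibration
    x_mm = record.time * 1000.0 / cal.ms_per_mm
    y_mm = sig / cal.mv_per_mm
    return x_mm, y_mm


def from_paper_mm(
    x_mm: np.ndarray, y_mm: np.ndarray, calibration: Calibration
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`to_paper_mm`: returns ``(t_ms, v_mV)``."""
    return (
        np.asarray(x_mm) * calibration.ms_per_mm,
        np.asarray(y_mm) * calibration.mv_per_mm,
    )


FEATURE_COLUMNS = [
    "patient_id",
    "beta_deg",
    "alpha_deg",
    "dbt5_ms",
    "dbtiso_ms",
    "ratio",
    "measurable_ii",
    "measurable_iii",
    "measurable_iv",
    "scbpt_label",
]
"""Column order of the per-patient feature CSV. Criterion columns are empty
(not zero) for patients without a measurable r'-wave; ``scbpt_label`` is
1 for a positive provocation test, 0 for negative, empty if unknown."""

_BOOL_COLS = ["measurable_ii", "measurable_iii", "measurable_iv"]
_VALUE_COLS = ["beta_deg", "alpha_deg", "dbt5_ms", "dbtiso_ms", "ratio"]


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    """Write a per-patient feature table as CSV.

    Unmeasurable criterion values must be NaN and are written as empty
    fields, never zeros, so that missingness survives a round-trip.
    """
    if len(features) == 0:
        raise ValueError("refusing to write an empty feature table")
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing}")
    out = features[FEATURE_COLUMNS].copy()
    for col in _BOOL_COLS:
        out[col] = out[col].astype(bool).astype(int)
    out.to_csv(path, index=False, float_format="%.9g", na_rep="")


def read_features(path: str | Path) -> pd.DataFrame:
    """Read a feature CSV written by :func:`write_features`."""
    frame = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing}")
    frame["patient_id"] = frame["patient_id"].astype(str)
    for col in _BOOL_COLS:
        frame[col] = frame[col].fillna(0).astype(int).astype(bool)
    for col in _VALUE_COLS:
        frame[col] = frame[col].astype(float)
    return frame


def any_measurable(features: pd.DataFrame) -> pd.Series:
    """Boolean series: patient has a measurable r' at any intercostal level."""
    return features[_BOOL_COLS].any(axis=1)
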