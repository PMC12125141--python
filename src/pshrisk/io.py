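"""Trend/waveform CSV I/O, missing-data handling and quality control.

All downstream stages operate on :class:`UniformSeries` — a regularly
sampled channel with explicit NaN missing markers — and on
:class:`TrendRecord`, the per-patient bundle of the five 60-s trend
channels (ABP, HR, BRS, ICP, PRx) over the first 72 h of monitoring.

Quality control mirrors standard multimodal-neuromonitoring practice:
gaps of at most ``max_run`` consecutive trend samples are linearly
interpolated, and a record is usable only if every channel retains at
most a 10% missing fraction afterwards.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "UniformSeries",
    "TrendRecord",
    "QCReport",
    "TREND_CHANNELS",
    "TREND_COLUMNS",
    "read_trend_csv",
    "write_trend_csv",
    "interpolate_gaps",
    "qc_record",
]

#: canonical channel order of a trend record
TREND_CHANNELS = ("abp", "hr", "brs", "icp", "prx")

#: CSV column names of the trend dialect, in file order
TREND_COLUMNS = (
    "timestamp_s",
    "abp_mmhg",
    "hr_bpm",
    "brs_ms_per_mmhg",
    "icp_mmhg",
    "prx",
)

_CHANNEL_TO_COLUMN = dict(zip(TREND_CHANNELS, TREND_COLUMNS[1:]))
_CHANNEL_UNITS = {
    "abp": "mmHg",
    "hr": "bpm",
    "brs": "ms/mmHg",
    "icp": "mmHg",
    "prx": "a.u.",
}


@dataclass
class UniformSeries:
    """A regularly sampled channel with explicit missing values (NaN)."""

    name: str
    start_time: float
    dt: float
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-D sequence")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times (seconds); samples are labeled by interval start."""
        return self.start_time + self.dt * np.arange(self.values.size)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def duration(self) -> float:
        """Total covered time in seconds (half-open interval convention)."""
        return self.dt * self.values.size

    def copy(self) -> "UniformSeries":
        return dataclasses.replace(self, values=self.values.copy())


@dataclass
class TrendRecord:
    """Per-patient 60-s trend channels on a shared time grid."""

    patient_id: str
    channels: dict[str, UniformSeries]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in TREND_CHANNELS if c not in self.channels]
        if missing:
            raise ValueError(f"trend record lacks channels: {missing}")
        ref = self.channels[TREND_CHANNELS[0]]
        for name, ch in self.channels.items():
            if (
                ch.dt != ref.dt
                or ch.start_time != ref.start_time
                or len(ch) != len(ref)
            ):
                raise ValueError(f"channel {name!r} is not on the shared grid")

    @property
    def dt(self) -> float:
        return self.channels[TREND_CHANNELS[0]].dt

    @property
    def n_samples(self) -> int:
        return len(self.channels[TREND_CHANNELS[0]])

    @property
    def duration_hours(self) -> float:
        return self.channels[TREND_CHANNELS[0]].duration / 3600.0

    def copy(self) -> "TrendRecord":
        return TrendRecord(
            patient_id=self.patient_id,
            channels={k: v.copy() for k, v in self.channels.items()},
            meta=dict(self.meta),
        )


@dataclass
class QCReport:
    """Per-channel missingness accounting after gap interpolation."""

    patient_id: str
    missing_fraction: dict[str, float]
    max_missing_run: dict[str, int]
    duration_hours: float
    passed: bool
    failed_channels: list[str]
    max_missing_frac: float
    required_hours: float


def write_trend_csv(record: TrendRecord, path: str | Path) -> Path:
    """Write a trend record in the documented CSV dialect.

    Missing samples are written as empty cells; the round trip through
    :func:`read_trend_csv` is lossless (values and missingness mask).
    """
    path = Path(path)
    ref = record.channels[TREND_CHANNELS[0]]
    data = {"timestamp_s": ref.times}
    for ch in TREND_CHANNELS:
        data[_CHANNEL_TO_COLUMN[ch]] = record.channels[ch].values
    frame = pd.DataFrame(data, columns=list(TREND_COLUMNS))
    frame.to_csv(path, index=False, float_format="%.17g", na_rep="")
    return path


def read_trend_csv(path: str | Path, patient_id: str | None = None) -> TrendRecord:
    """Read a trend CSV, validating the header and the regular time grid."""
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    if tuple(frame.columns) != TREND_COLUMNS:
        raise ValueError(
            f"{path}: unexpected header {tuple(frame.columns)}; "
            f"expected {TREND_COLUMNS}"
        )
    ts = frame["timestamp_s"].to_numpy(dtype=float)
    if ts.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    steps = np.diff(ts)
    if np.any(steps <= 0):
        row = int(np.argmax(steps <= 0)) + 2  # +1 header, +1 next row
        raise ValueError(f"{path}: non-monotone timestamps at data row {row}")
    dt = steps[0]
    bad = np.nonzero(~np.isclose(steps, dt, rtol=0, atol=1e-6 * dt))[0]
    if bad.size:
        row = int(bad[0]) + 2
        raise ValueError(f"{path}: irregular time grid at data row {row}")
    channels = {
        ch: UniformSeries(
            name=ch,
            start_time=float(ts[0]),
            dt=float(dt),
            values=frame[_CHANNEL_TO_COLUMN[ch]].to_numpy(dtype=float),
            units=_CHANNEL_UNITS[ch],
        )
        for ch in TREND_CHANNELS
    }
    return TrendRecord(patient_id=patient_id or path.stem, channels=channels)


def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Return (start, length) of each maximal run of True in ``mask``."""
    runs: list[tuple[int, int]] = []
    n = mask.size
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def interpolate_gaps(series: UniformSeries, max_run: int = 10) -> UniformSeries:
    """Linearly fill interior missing runs of length <= ``max_run``.

    Runs longer than ``max_run`` and runs touching either boundary (no
    anchor on one side) are left missing. Observed values are never
    altered, and the operation is idempotent.
    """
    out = series.copy()
    v = out.values
    for start, length in _missing_runs(np.isnan(v)):
        if length > max_run:
            continue
        left, right = start - 1, start + length
        if left < 0 or right >= v.size:
            continue  # boundary run: no anchor
        v[start:right] = np.interp(
            np.arange(start, right), [left, right], [v[left], v[right]]
        )
    return out


def qc_record(
    record: TrendRecord,
    max_missing_frac: float = 0.10,
    required_hours: float = 72.0,
    interp_max_run: int = 10,
) -> QCReport:
    """Quality-control a trend record after gap interpolation.

    A record passes when it covers ``required_hours`` and every channel's
    residual missing fraction (after :func:`interpolate_gaps`) is at most
    ``max_missing_frac``. Failure of any channel fails the record.
    """
    missing_fraction: dict[str, float] = {}
    max_missing_run: dict[str, int] = {}
    failed: list[str] = []
    for ch in TREND_CHANNELS:
        filled = interpolate_gaps(record.channels[ch], max_run=interp_max_run)
        mask = filled.missing_mask
        frac = float(mask.mean())
        runs = _missing_runs(mask)
        missing_fraction[ch] = frac
        max_missing_run[ch] = max((length for _, length in runs), default=0)
        if frac > max_missing_frac:
            failed.append(ch)
    duration_hours = record.duration_hours
    passed = not failed and duration_hours >= required_hours - 1e-9
    return QCReport(
        patient_id=record.patient_id,
        missing_fraction=missing_fraction,
        max_missing_run=max_missing_run,
        duration_hours=duration_hours,
        passed=passed,
        failed_channels=failed,
        max_missing_frac=max_missing_frac,
        required_hours=required_hours,
    )
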