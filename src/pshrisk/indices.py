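"""Neuromonitoring indices derived from raw ABP/ICP waveforms.

Implements the standard trend parameters used in multimodal
neuromonitoring of traumatic brain injury:

* heart rate (HR) from the first cardiac harmonic of the ABP spectrum
  (40–140 bpm search band),
* baroreflex sensitivity (BRS) by the time-domain cross-correlation
  method: the regression slope between 10-s segments of the interbeat
  interval and systolic pressure series at the lag (0–5 s) maximizing
  their correlation,
* the pressure reactivity index (PRx): Pearson correlation between
  slow waves of ABP and ICP over a 5-min window of 10-s means, updated
  every 10 s,

and the 60-s trend averaging that puts all of them on the common grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import UniformSeries, TrendRecord, TREND_CHANNELS

__all__ = [
    "WaveformRecord",
    "BeatSeries",
    "estimate_hr_fft",
    "detect_beats",
    "estimate_brs_xcorr",
    "brs_segment_slopes",
    "compute_prx",
    "trend_average",
    "waveform_to_trend",
    "HR_BAND_HZ",
]

#: 40–140 bpm cardiac search band
HR_BAND_HZ = (0.67, 2.33)


@dataclass
class WaveformRecord:
    """Co-registered raw ABP and ICP waveforms (typically 200 Hz)."""

    patient_id: str
    abp: UniformSeries
    icp: UniformSeries
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (
            self.abp.dt != self.icp.dt
            or self.abp.start_time != self.icp.start_time
            or len(self.abp) != len(self.icp)
        ):
            raise ValueError("ABP and ICP waveforms must share the time grid")

    @property
    def fs(self) -> float:
        return 1.0 / self.abp.dt


@dataclass
class BeatSeries:
    """Beat-wise systolic pressure and interbeat intervals.

    ``ibi[k]`` is the interval ending at ``beat_times[k]`` in ms; the
    first beat has no preceding interval and carries NaN.
    """

    beat_times: np.ndarray
    sbp: np.ndarray
    ibi: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.sbp = np.asarray(self.sbp, dtype=float)
        self.ibi = np.asarray(self.ibi, dtype=float)
        if self.beat_times.size and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")

    def __len__(self) -> int:
        return self.beat_times.size


def estimate_hr_fft(
    segment: UniformSeries,
    band: tuple[float, float] = HR_BAND_HZ,
    min_duration_s: float = 30.0,
    peak_floor: float = 5.0,
) -> float:
    """Heart rate (bpm) from the first cardiac harmonic of an ABP segment.

    The segment is detrended and Hann-windowed; the magnitude spectrum is
    searched within ``band`` (Hz) and HR = 60 x the argmax frequency.
    Returns NaN when the segment is too short or there is no credible
    cardiac component: the in-band peak must rise above ``peak_floor`` x
    the median in-band magnitude and reach at least 20% of the global
    non-DC spectral peak (guards against pure leakage from a strong
    out-of-band tone, e.g. respiration).
    """
    x = segment.values
    if segment.duration < min_duration_s or np.isnan(x).any():
        return np.nan
    x = sps.detrend(x)
    if np.ptp(x) == 0:
        return np.nan
    w = np.hanning(x.size)
    spec = np.abs(np.fft.rfft(x * w))
    freqs = np.fft.rfftfreq(x.size, d=segment.dt)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        return np.nan
    in_band = spec[sel]
    peak = in_band.max()
    floor = np.median(in_band)
    global_peak = spec[freqs > 0.1].max()
    if floor == 0 or peak < peak_floor * floor or peak < 0.2 * global_peak:
        return np.nan
    return 60.0 * float(freqs[sel][np.argmax(in_band)])


def detect_beats(
    abp: UniformSeries,
    refractory_s: float = 0.25,
    prominence_frac: float = 0.3,
) -> BeatSeries:
    """Detect systolic peaks in an ABP waveform.

    Local maxima separated by at least ``refractory_s`` with prominence
    of at least ``prominence_frac`` x the signal's peak-to-peak range.
    A flat signal yields an empty series.
    """
    x = abp.values
    ptp = np.ptp(x[~np.isnan(x)]) if (~np.isnan(x)).any() else 0.0
    if ptp == 0:
        empty = np.empty(0)
        return BeatSeries(empty, empty.copy(), empty.copy())
    distance = max(1, int(round(refractory_s / abp.dt)))
    peaks, _ = sps.find_peaks(x, distance=distance, prominence=prominence_frac * ptp)
    times = abp.start_time + abp.dt * peaks
    sbp = x[peaks]
    ibi = np.full(peaks.size, np.nan)
    if peaks.size > 1:
        ibi[1:] = np.diff(times) * 1000.0
    return BeatSeries(times, sbp, ibi)


def _beats_to_1s_grid(beats: BeatSeries) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resample beat-wise SBP and IBI to a 1-s grid by linear interpolation."""
    t = beats.beat_times
    valid = ~np.isnan(beats.ibi)
    t0 = np.ceil(t[0])
    t1 = np.floor(t[-1])
    grid = np.arange(t0, t1 + 0.5)
    sbp = np.interp(grid, t, beats.sbp)
    ibi = np.interp(grid, t[valid], beats.ibi[valid])
    return grid, sbp, ibi


def brs_segment_slopes(
    beats: BeatSeries,
    segment_s: int = 10,
    max_lag_s: int = 5,
    require_positive: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-segment BRS estimates by the cross-correlation method.

    SBP and IBI beat series are resampled to a 1-s grid; over each
    non-overlapping ``segment_s`` segment, the correlation between IBI
    and SBP delayed by each integer lag in ``0..max_lag_s`` s is
    evaluated, and the regression slope of IBI on SBP is taken at the
    maximizing lag. Segments whose best correlation is not positive (if
    ``require_positive``) or with zero variance are NaN.

    Returns ``(segment_start_times, slopes_ms_per_mmhg, chosen_lags)``.
    """
    if len(beats) < 3:
        return np.empty(0), np.empty(0), np.empty(0)
    grid, sbp, ibi = _beats_to_1s_grid(beats)
    n_seg = (grid.size - max_lag_s) // segment_s
    starts = np.empty(n_seg)
    slopes = np.full(n_seg, np.nan)
    lags = np.full(n_seg, np.nan)
    for s in range(n_seg):
        # IBI segment sits after the lag search range so every lag is usable
        i0 = max_lag_s + s * segment_s
        ib = ibi[i0 : i0 + segment_s]
        starts[s] = grid[i0]
        if np.std(ib) == 0:
            continue
        best_r, best_lag = -np.inf, None
        for lag in range(max_lag_s + 1):
            sb = sbp[i0 - lag : i0 - lag + segment_s]
            if np.std(sb) == 0:
                continue
            r = np.corrcoef(ib, sb)[0, 1]
            if r > best_r:
                best_r, best_lag = r, lag
        if best_lag is None or (require_positive and best_r <= 0):
            continue
        sb = sbp[i0 - best_lag : i0 - best_lag + segment_s]
        slope = np.polyfit(sb, ib, 1)[0]
        slopes[s] = slope
        lags[s] = best_lag
    return starts, slopes, lags


def estimate_brs_xcorr(
    beats: BeatSeries,
    segment_s: int = 10,
    max_lag_s: int = 5,
    require_positive: bool = True,
) -> float:
    """Mean BRS (ms/mmHg) over all valid 10-s segments; NaN if none."""
    _, slopes, _ = brs_segment_slopes(
        beats, segment_s=segment_s, max_lag_s=max_lag_s,
        require_positive=require_positive,
    )
    if slopes.size == 0 or np.isnan(slopes).all():
        return np.nan
    return float(np.nanmean(slopes))


def compute_prx(
    abp: UniformSeries,
    icp: UniformSeries,
    block_s: float = 10.0,
    n_blocks: int = 30,
) -> UniformSeries:
    """Pressure reactivity index as a 10-s-updated series.

    Both channels are reduced to ``block_s`` means (slow-wave filtering);
    PRx at block k is the Pearson correlation of the ``n_blocks`` most
    recent means (a 5-min window for the 10-s/30-block default). The
    value is emitted every ``block_s`` seconds, labeled by the start of
    the last contributing block; windows with zero variance are NaN.
    """
    if abp.dt != icp.dt or len(abp) != len(icp):
        raise ValueError("ABP and ICP must share the time grid")
    per_block = block_s / abp.dt
    if abs(per_block - round(per_block)) > 1e-9:
        raise ValueError("sample interval must divide the block length")
    per_block = int(round(per_block))
    n = (len(abp) // per_block) * per_block
    a = abp.values[:n].reshape(-1, per_block).mean(axis=1)
    b = icp.values[:n].reshape(-1, per_block).mean(axis=1)
    k = a.size
    prx = np.full(k, np.nan)
    for i in range(n_blocks - 1, k):
        aw = a[i - n_blocks + 1 : i + 1]
        bw = b[i - n_blocks + 1 : i + 1]
        if np.isnan(aw).any() or np.isnan(bw).any():
            continue
        if np.std(aw) == 0 or np.std(bw) == 0:
            continue
        prx[i] = np.corrcoef(aw, bw)[0, 1]
    return UniformSeries(
        name="prx", start_time=abp.start_time, dt=block_s, values=prx, units="a.u."
    )


def trend_average(
    series: UniformSeries, window_s: float = 60.0, max_missing_frac: float = 0.5
) -> UniformSeries:
    """Non-overlapping window means on the trend grid.

    A bin with more than ``max_missing_frac`` missing source samples is
    missing. Partial trailing bins are dropped.
    """
    per_bin = window_s / series.dt
    if abs(per_bin - round(per_bin)) > 1e-9:
        raise ValueError("sample interval must divide the averaging window")
    per_bin = int(round(per_bin))
    n = (len(series) // per_bin) * per_bin
    if n == 0:
        raise ValueError("series shorter than one averaging window")
    blocks = series.values[:n].reshape(-1, per_bin)
    counts = (~np.isnan(blocks)).sum(axis=1)
    means = np.where(
        counts > 0, np.nansum(blocks, axis=1) / np.maximum(counts, 1), np.nan)
    means[counts < (1 - max_missing_frac) * per_bin] = np.nan
    return UniformSeries(
        name=series.name,
        start_time=series.start_time,
        dt=window_s,
        values=means,
        units=series.units,
    )


def waveform_to_trend(record: WaveformRecord, trend_dt: float = 60.0) -> TrendRecord:
    """Derive the five 60-s trend channels from a raw waveform record.

    ABP and ICP are 60-s means of the raw pressures; HR is estimated per
    60-s segment from the ABP spectrum; BRS segment estimates are
    averaged into each 60-s bin; PRx is computed at 10-s updates and
    averaged onto the trend grid.
    """
    abp, icp = record.abp, record.icp
    per_bin = int(round(trend_dt / abp.dt))
    n_bins = len(abp) // per_bin

    abp_trend = trend_average(abp, window_s=trend_dt)
    icp_trend = trend_average(icp, window_s=trend_dt)

    hr = np.full(n_bins, np.nan)
    for b in range(n_bins):
        seg = UniformSeries(
            name="abp",
            start_time=abp.start_time + b * trend_dt,
            dt=abp.dt,
            values=abp.values[b * per_bin : (b + 1) * per_bin],
            units=abp.units,
        )
        hr[b] = estimate_hr_fft(seg)

    beats = detect_beats(abp)
    brs = np.full(n_bins, np.nan)
    if len(beats) >= 3:
        starts, slopes, _ = brs_segment_slopes(beats)
        rel = starts - abp.start_time
        for b in range(n_bins):
            sel = (rel >= b * trend_dt) & (rel < (b + 1) * trend_dt)
            if sel.any() and not np.isnan(slopes[sel]).all():
                brs[b] = np.nanmean(slopes[sel])

    prx10 = compute_prx(abp, icp)
    prx = trend_average(prx10, window_s=trend_dt)
    prx_vals = np.full(n_bins, np.nan)
    prx_vals[: min(n_bins, len(prx))] = prx.values[:n_bins]

    def us(name: str, vals: np.ndarray, units: str) -> UniformSeries:
        return UniformSeries(
            name=name, start_time=abp.start_time, dt=trend_dt,
            values=vals[:n_bins], units=units,
        )

    channels = {
        "abp": us("abp", abp_trend.values, "mmHg"),
        "hr": us("hr", hr, "bpm"),
        "brs": us("brs", brs, "ms/mmHg"),
        "icp": us("icp", icp_trend.values, "mmHg"),
        "prx": us("prx", prx_vals, "a.u."),
    }
    assert set(channels) == set(TREND_CHANNELS)
    return TrendRecord(patient_id=record.patient_id, channels=channels)
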