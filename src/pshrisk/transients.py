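"""Rolling ANS-hemodynamics correlations and their variability metrics.

The core transient construct: for each of the six pairs of an autonomic
channel (HR, ABP, BRS) with a cerebral-hemodynamic channel (ICP, PRx),
a rolling Pearson correlation is computed on the 60-s trend grid over a
sliding window of 3, 6, 12 or 24 h, stepping one sample at a time. The
72-h axis is then divided into consecutive bins of the same length, and
three variability metrics summarize the correlation values within each
bin:

* MEAN — mean correlation,
* STD  — sample standard deviation of the correlation,
* ZCR  — zero-crossing rate, how often the correlation changes sign:

      ZCR = 1/(N-1) * sum_{n=1}^{N-1} |sgn(corr[n]) - sgn(corr[n-1])|

with sgn(0) = 0, so ZCR lies in [0, 2].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import UniformSeries

__all__ = [
    "CorrelationTrack",
    "VariabilityFeature",
    "ANS_CHANNELS",
    "HEMO_CHANNELS",
    "SIGNAL_PAIRS",
    "WINDOW_HOURS",
    "METRICS",
    "rolling_correlation",
    "zcr",
    "variability_metrics",
    "n_bins_for_window",
]

ANS_CHANNELS = ("abp", "hr", "brs")
HEMO_CHANNELS = ("icp", "prx")
#: the six analyzed pairs, in deterministic column order
SIGNAL_PAIRS = tuple((a, h) for a in ANS_CHANNELS for h in HEMO_CHANNELS)
WINDOW_HOURS = (3, 6, 12, 24)
METRICS = ("zcr", "std", "mean")


@dataclass
class CorrelationTrack:
    """Rolling correlation of one signal pair at one window length.

    ``corr[s]`` is the Pearson correlation over samples ``[s, s+W)``;
    values are labeled by window *start* time, so only windows fully
    inside the record exist. NaN marks windows failing the completeness
    gate or with zero variance.
    """

    pair: tuple[str, str]
    window_hours: float
    times: np.ndarray          # seconds, window start
    corr: np.ndarray
    duration_hours: float      # of the underlying record

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.corr = np.asarray(self.corr, dtype=float)
        if self.times.shape != self.corr.shape:
            raise ValueError("times and corr must have equal length")


@dataclass
class VariabilityFeature:
    pair: tuple[str, str]
    window_hours: float
    metric: str
    bin_index: int
    bin_start_hours: float
    value: float


def rolling_correlation(
    x: UniformSeries,
    y: UniformSeries,
    window_hours: float,
    min_valid: float = 0.9,
) -> CorrelationTrack:
    """Rolling Pearson correlation on the shared trend grid, step one sample.

    Within each window, pairwise-complete samples are used; a window is
    missing when the complete-pair fraction is below ``min_valid`` or
    either channel has (numerically) zero variance within the window.
    """
    if x.dt != y.dt or x.start_time != y.start_time or len(x) != len(y):
        raise ValueError("x and y must share the time grid")
    w = int(round(window_hours * 3600.0 / x.dt))
    n = len(x)
    if w < 2 or w > n:
        raise ValueError("window must cover >= 2 samples and fit in the record")

    # center by global nanmean for numerical stability of cumulative sums;
    # Pearson correlation is invariant to the shift
    xv = x.values - np.nanmean(x.values)
    yv = y.values - np.nanmean(y.values)
    ok = ~(np.isnan(xv) | np.isnan(yv))
    x0 = np.where(ok, xv, 0.0)
    y0 = np.where(ok, yv, 0.0)

    def wsum(a: np.ndarray) -> np.ndarray:
        c = np.concatenate(([0.0], np.cumsum(a)))
        return c[w:] - c[:-w]

    cnt = wsum(ok.astype(float))
    sx, sy = wsum(x0), wsum(y0)
    sxx, syy, sxy = wsum(x0 * x0), wsum(y0 * y0), wsum(x0 * y0)

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / cnt
        vx = sxx - sx * sx / cnt
        vy = syy - sy * sy / cnt
        corr = cov / np.sqrt(vx * vy)

    scale_x = max(float(np.max(np.abs(xv[ok]), initial=0.0)), 1.0) ** 2
    scale_y = max(float(np.max(np.abs(yv[ok]), initial=0.0)), 1.0) ** 2
    bad = (
        (cnt < min_valid * w)
        | (vx <= 1e-12 * scale_x * w)
        | (vy <= 1e-12 * scale_y * w)
    )
    corr = np.where(bad, np.nan, corr)
    corr = np.clip(corr, -1.0, 1.0)

    times = x.start_time + x.dt * np.arange(n - w + 1)
    return CorrelationTrack(
        pair=(x.name, y.name),
        window_hours=window_hours,
        times=times,
        corr=corr,
        duration_hours=x.duration / 3600.0,
    )


def zcr(corr: np.ndarray) -> float:
    """Zero-crossing rate of a correlation sequence.

    Missing values are dropped before pairing consecutive samples; with
    fewer than two defined values the statistic is undefined (NaN).
    sgn(0) = 0, so a touch of zero contributes 1 per adjacent pair and
    the statistic lies in [0, 2].
    """
    v = np.asarray(corr, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        return np.nan
    s = np.sign(v)
    return float(np.abs(np.diff(s)).sum() / (v.size - 1))


def n_bins_for_window(duration_hours: float, window_hours: float) -> int:
    return int(np.ceil(duration_hours / window_hours))


def variability_metrics(track: CorrelationTrack) -> list[VariabilityFeature]:
    """MEAN/STD/ZCR per consecutive non-overlapping bin of the track.

    Bins have the same length as the correlation window and are anchored
    at the record start; a correlation value belongs to the bin
    containing its window-start time. Bins with fewer than two defined
    values yield NaN for all three metrics (STD is the sample standard
    deviation and needs two points; the bins are treated uniformly).
    """
    w_h = track.window_hours
    nb = n_bins_for_window(track.duration_hours, w_h)
    start_h = track.times / 3600.0
    out: list[VariabilityFeature] = []
    for b in range(nb):
        lo, hi = b * w_h, (b + 1) * w_h
        sel = (start_h >= lo) & (start_h < hi)
        vals = track.corr[sel]
        vals = vals[~np.isnan(vals)]
        if vals.size < 2:
            mean = std = z = np.nan
        else:
            mean = float(np.mean(vals))
            std = float(np.std(vals, ddof=1))
            z = zcr(vals)
        for metric, value in (("mean", mean), ("std", std), ("zcr", z)):
            out.append(VariabilityFeature(
                pair=track.pair, window_hours=w_h, metric=metric,
                bin_index=b, bin_start_hours=lo, value=value,
            ))
    return out
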