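"""Synthetic cohort generator for the PSH-risk analysis pipeline.

No public monitoring dataset accompanies the problem this package
addresses, so all pipeline-level testing runs on a synthetic cohort that
reproduces the *statistical structure* the analysis assumes, not the
physiology of any real patient:

* a 41-patient cohort (14 "at risk of PSH") with clinical metadata drawn
  from location/scale families matched to the published cohort's
  medians/IQRs and flag rates (group-dependent white-blood-cell count is
  the one real metadata signal);
* five 60-s trend channels (ABP, HR, BRS, ICP, PRx) over 72 h whose
  pairwise coupling sign follows a latent two-state Poisson switching
  process — at-risk patients switch faster, concentrated in an early
  effect window, so that the zero-crossing rate of the rolling
  correlation is the injected group difference;
* optional raw 200-Hz ABP/ICP waveform segments with a known cardiac
  fundamental, baroreflex gain/delay and ABP–ICP slow-wave coupling, used
  to close the loop on the waveform-level estimators.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import UniformSeries, TrendRecord, TREND_CHANNELS
from .indices import WaveformRecord

__all__ = [
    "WaveformParams",
    "ChannelSpec",
    "CouplingSpec",
    "GroupStats",
    "MetadataParams",
    "MissingSpec",
    "CohortParams",
    "gen_waveform",
    "gen_trend_record",
    "gen_metadata",
    "inject_gaps",
    "gen_cohort",
    "METADATA_COLUMNS",
]


# --------------------------------------------------------------------------
# waveform level
# --------------------------------------------------------------------------

@dataclass
class WaveformParams:
    """Ground-truth parameters of a synthetic 200-Hz ABP/ICP segment."""

    duration: float = 120.0          # s
    sampling_rate: float = 200.0     # Hz
    mean_abp: float = 84.0           # mmHg
    pulse_freq: float = 1.3          # Hz, cardiac fundamental
    pulse_amp: float = 20.0          # mmHg, systolic upstroke height
    resp_freq: float = 0.25          # Hz
    resp_amp: float = 2.0            # mmHg
    mayer_freq: float = 0.1          # Hz
    mayer_amp: float = 1.5           # mmHg
    slow_band: tuple[float, float] = (0.005, 0.05)  # Hz
    slow_amp: float = 2.0            # mmHg (sd of slow component)
    brs_gain: float = 6.0            # ms/mmHg
    brs_delay: float = 1.0           # s, within the 0-5 s estimator range
    icp_mean: float = 11.0           # mmHg
    icp_slow_coupling: float = 0.5   # in [-1, 1]
    noise_sd: float = 0.0            # mmHg
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling_rate must be positive")
        if self.sampling_rate <= 2 * self.pulse_freq:
            raise ValueError("sampling_rate must exceed twice the pulse frequency")
        if not 0 <= self.brs_delay <= 5:
            raise ValueError("brs_delay must lie in the 0-5 s estimator range")
        if not -1 <= self.icp_slow_coupling <= 1:
            raise ValueError("icp_slow_coupling must lie in [-1, 1]")


def _slow_component(t: np.ndarray, band: tuple[float, float], amp: float,
                    rng: np.random.Generator, n_tones: int = 8) -> np.ndarray:
    """Band-limited slow oscillation as a random sum of sinusoids with sd ~= amp."""
    if amp == 0:
        return np.zeros_like(t)
    freqs = rng.uniform(band[0], band[1], n_tones)
    phases = rng.uniform(0, 2 * np.pi, n_tones)
    # independent phases: per-tone variance a^2/2, choose a for total sd = amp
    a = amp * np.sqrt(2.0 / n_tones)
    return (a * np.sin(2 * np.pi * freqs[:, None] * t + phases[:, None])).sum(axis=0)


# zero-mean periodic pulse shape, peak value at phase 0
_PULSE_HARMONICS = (0.6, 0.3, 0.1)


def _pulse_shape(phase: np.ndarray) -> np.ndarray:
    out = np.zeros_like(phase)
    for h, a in enumerate(_PULSE_HARMONICS, start=1):
        out += a * np.cos(2 * np.pi * h * phase)
    return out


def gen_waveform(params: WaveformParams) -> WaveformRecord:
    """Generate a raw ABP/ICP waveform segment with known ground truth.

    The ABP channel is a baseline plus a zero-mean pulse train at the
    cardiac fundamental, respiratory and Mayer sinusoids, a band-limited
    slow component and white noise. Beat timing is modulated so that the
    interbeat interval responds to systolic pressure with slope
    ``brs_gain`` (ms/mmHg) at lag ``brs_delay``. The ICP channel shares
    the slow component scaled by ``icp_slow_coupling`` plus its own
    noise. Ground truth (beat times, per-beat SBP/IBI, the slow wave) is
    attached for recovery tests.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    fs = p.sampling_rate
    t = np.arange(0.0, p.duration, 1.0 / fs)

    slow = _slow_component(t, p.slow_band, p.slow_amp, rng)

    def modulation(times: np.ndarray) -> np.ndarray:
        m = p.resp_amp * np.sin(2 * np.pi * p.resp_freq * times)
        m += p.mayer_amp * np.sin(2 * np.pi * p.mayer_freq * times)
        m += np.interp(times, t, slow, left=slow[0], right=slow[-1])
        return m

    # beat times: IBI ending at beat k responds to SBP modulation at lag
    base_ibi = 1.0 / p.pulse_freq  # s
    beat_times = [0.0]
    drives = [np.nan]  # modulation value each interval responded to
    while beat_times[-1] < p.duration:
        t_prev = beat_times[-1]
        t_pred = t_prev + base_ibi  # slow modulation: implicit solve unnecessary
        m_lag = modulation(np.array([max(0.0, t_pred - p.brs_delay)]))[0]
        ibi = base_ibi + (p.brs_gain / 1000.0) * m_lag
        beat_times.append(t_prev + max(0.2, ibi))
        drives.append(m_lag)
    beat_times = np.asarray(beat_times)
    drives = np.asarray(drives)
    in_range = beat_times < p.duration
    beat_times_in = beat_times[in_range]
    drives_in = drives[in_range]

    # phase within the current beat, for the pulse train
    idx = np.searchsorted(beat_times, t, side="right") - 1
    idx = np.clip(idx, 0, beat_times.size - 2)
    ibi_here = beat_times[idx + 1] - beat_times[idx]
    phase = (t - beat_times[idx]) / ibi_here

    m_t = modulation(t)
    abp = p.mean_abp + m_t + p.pulse_amp * _pulse_shape(phase)
    abp = abp + rng.normal(0, p.noise_sd, t.size) if p.noise_sd else abp

    icp = p.icp_mean + p.icp_slow_coupling * slow
    icp = icp + rng.normal(0, 0.5 * p.noise_sd, t.size) if p.noise_sd else icp

    pulse_peak = p.pulse_amp * _pulse_shape(np.zeros(1))[0]
    sbp = p.mean_abp + modulation(beat_times_in) + pulse_peak
    ibi_ms = np.full(beat_times_in.size, np.nan)
    if beat_times_in.size > 1:
        ibi_ms[1:] = np.diff(beat_times_in) * 1000.0

    ground_truth = {
        "params": p,
        "beat_times": beat_times_in,
        "sbp": sbp,
        # SBP value whose deviation each interval responded to (lagged)
        "sbp_drive": p.mean_abp + pulse_peak + drives_in,
        "ibi_ms": ibi_ms,
        "slow": slow,
        "t": t,
    }
    mk = lambda name, v, u: UniformSeries(name, 0.0, 1.0 / fs, v, u)
    return WaveformRecord(
        patient_id="synthetic",
        abp=mk("abp", abp, "mmHg"),
        icp=mk("icp", icp, "mmHg"),
        ground_truth=ground_truth,
    )


# --------------------------------------------------------------------------
# cohort level
# --------------------------------------------------------------------------

@dataclass
class ChannelSpec:
    """Location/scale of one trend channel: between-patient and within-record."""

    loc: float
    between_sd: float
    within_sd: float


@dataclass
class CouplingSpec:
    """Latent sign-switching coupling between an ANS and a hemodynamic channel.

    The short-horizon correlation between the pair tracks a latent +/-
    sign that switches according to a Poisson process. Not-at-risk
    patients switch at ``rate_baseline`` throughout; at-risk patients
    switch at ``rate_at_risk`` inside ``effect_span_hours`` (the whole
    record if None) and at the baseline rate elsewhere. ``coupling`` is
    the stable-sign correlation magnitude.
    """

    ans: str
    hemo: str
    coupling: float = 0.4
    rate_baseline: float = 0.0      # switches / hour: stable coupling sign
    rate_at_risk: float = 20.0      # switches / hour: unstable coupling
    effect_span_hours: tuple[float, float] | None = (0.0, 3.0)

    def __post_init__(self) -> None:
        if not 0 <= self.coupling <= 1:
            raise ValueError("coupling magnitude must lie in [0, 1]")
        if self.rate_baseline < 0 or self.rate_at_risk < 0:
            raise ValueError("switch rates must be non-negative")


@dataclass
class GroupStats:
    """(at_risk, not_at_risk) parameter pairs for one metadata variable."""

    at_risk: tuple[float, ...]
    not_at_risk: tuple[float, ...]

    def for_group(self, at_risk: bool) -> tuple[float, ...]:
        return self.at_risk if at_risk else self.not_at_risk


def _lognorm_from_median_iqr(median: float, q25: float, q75: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal matching a printed median and IQR."""
    mu = np.log(median)
    sigma = np.log(q75 / q25) / (2 * 0.6744897501960817)  # 2*z_{0.75}
    return mu, sigma


@dataclass
class MetadataParams:
    """Families matched to the reference cohort's medians/IQRs and rates.

    Continuous skewed variables (age, WBC) are log-normal; Hb is normal;
    ordinal scores (GCS, ISS) are discrete uniform over the printed IQR;
    flags are Bernoulli. Only WBC is group-dependent: it was the one
    metadata variable with a significant group difference in the
    reference cohort, so the other variables use the whole-cohort
    distribution for both groups (their printed per-group spreads are
    treated as sampling noise, not population structure).
    """

    age: GroupStats = field(default_factory=lambda: GroupStats(
        _lognorm_from_median_iqr(33, 28, 50), _lognorm_from_median_iqr(33, 28, 50)))
    female_rate: GroupStats = field(default_factory=lambda: GroupStats((0.24,), (0.24,)))
    gcs_range: GroupStats = field(default_factory=lambda: GroupStats((4, 8), (4, 8)))
    iss_range: GroupStats = field(default_factory=lambda: GroupStats((20, 34), (20, 34)))
    multiorgan_rate: GroupStats = field(default_factory=lambda: GroupStats((0.61,), (0.61,)))
    hb: GroupStats = field(default_factory=lambda: GroupStats(
        (13.1, (14.4 - 11.3) / 1.349), (13.1, (14.4 - 11.3) / 1.349)))
    wbc: GroupStats = field(default_factory=lambda: GroupStats(
        _lognorm_from_median_iqr(20.3, 15.8, 21.9),
        _lognorm_from_median_iqr(14.2, 10.1, 17.4)))
    ct_rates: dict[str, GroupStats] = field(default_factory=lambda: {
        "ct_sdh": GroupStats((0.46,), (0.46,)),
        "ct_edh": GroupStats((0.05,), (0.05,)),
        "ct_tich": GroupStats((0.22,), (0.22,)),
        "ct_edema": GroupStats((0.68,), (0.68,)),
        "ct_dai": GroupStats((0.80,), (0.80,)),
        "ct_tsah": GroupStats((0.54,), (0.54,)),
    })


@dataclass
class MissingSpec:
    """Where to punch missing runs into a trend record.

    Either ``gap_lengths`` (explicit run lengths, placed uniformly at
    random without overlap, applied to every channel independently) or
    ``fraction`` (total missing fraction, reached with runs drawn
    uniformly from ``gap_length_range``). Empty spec = identity.
    """

    fraction: float | None = None
    gap_length_range: tuple[int, int] = (2, 8)
    gap_lengths: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.fraction is not None and not 0 <= self.fraction <= 1:
            raise ValueError("missing fraction must lie in [0, 1]")

    @property
    def empty(self) -> bool:
        return self.fraction in (None, 0) and not self.gap_lengths


METADATA_COLUMNS = (
    "patient_id", "psh_risk", "age", "sex_male", "gcs_sum", "iss",
    "trauma_multiorgan", "hb", "wbc",
    "ct_sdh", "ct_edh", "ct_tich", "ct_edema", "ct_dai", "ct_tsah",
)


@dataclass
class CohortParams:
    """Study conditions of the default synthetic cohort."""

    n_patients: int = 41
    n_at_risk: int = 14
    duration_hours: float = 72.0
    trend_dt_s: float = 60.0
    channel_baselines: dict[str, ChannelSpec] = field(default_factory=lambda: {
        "abp": ChannelSpec(84.0, 6.0, 4.0),
        "hr": ChannelSpec(78.0, 8.0, 5.0),
        "brs": ChannelSpec(6.8, 2.5, 1.5),
        "icp": ChannelSpec(11.0, 3.0, 2.0),
        "prx": ChannelSpec(0.05, 0.08, 0.15),
    })
    coupling_pairs: tuple[CouplingSpec, ...] = (
        # every ANS-hemodynamics pair is weakly coupled with a stable
        # sign; only the HR pairs switch, early, in the at-risk group
        CouplingSpec(ans="abp", hemo="icp", coupling=0.3, rate_at_risk=0.0),
        CouplingSpec(ans="abp", hemo="prx", coupling=0.3, rate_at_risk=0.0),
        CouplingSpec(ans="hr", hemo="icp", coupling=0.3),
        CouplingSpec(ans="hr", hemo="prx", coupling=0.3),
        CouplingSpec(ans="brs", hemo="icp", coupling=0.3, rate_at_risk=0.0),
        CouplingSpec(ans="brs", hemo="prx", coupling=0.3, rate_at_risk=0.0),
    )
    metadata: MetadataParams = field(default_factory=MetadataParams)
    missing: MissingSpec = field(default_factory=lambda: MissingSpec(fraction=0.03))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_at_risk <= self.n_patients:
            raise ValueError("n_at_risk must not exceed n_patients")
        for ch in TREND_CHANNELS:
            load = sum(cp.coupling for cp in self.coupling_pairs
                       if ch in (cp.ans, cp.hemo))
            if load > 1 + 1e-9:
                raise ValueError(
                    f"total coupling magnitude on channel {ch!r} exceeds 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_hours * 3600 / self.trend_dt_s))


def _switch_sign_process(n: int, dt_hours: float, rate_fn, rng) -> tuple[np.ndarray, np.ndarray]:
    """Latent +/-1 process from a piecewise-constant-rate Poisson clock.

    ``rate_fn(hour)`` gives the instantaneous switch rate; rates are
    treated as constant within each sample. Returns (signs, switch_times_h).
    """
    hours = dt_hours * np.arange(n)
    rates = np.asarray([rate_fn(h) for h in hours])
    # thinning-free simulation: number of switches per sample interval
    n_sw = rng.poisson(rates * dt_hours)
    signs = np.empty(n)
    s = 1.0
    switch_times = []
    for i in range(n):
        if n_sw[i] % 2 == 1:
            s = -s
        if n_sw[i] > 0:
            switch_times.append(hours[i])
        signs[i] = s
    return signs, np.asarray(switch_times)


def gen_trend_record(
    cohort_params: CohortParams,
    patient_index: int,
    at_risk: bool,
    rng: np.random.Generator | None = None,
) -> TrendRecord:
    """Generate one patient's 72-h trend record with latent coupling.

    Each coupled pair shares a latent standard-normal driver; the
    hemodynamic side is multiplied by the pair's switching sign, so the
    short-horizon correlation of the pair tracks the latent sign at the
    configured magnitude. Residual channel variance is independent noise.
    Ground-truth switch times are stored in ``record.meta``.
    """
    cp = cohort_params
    if patient_index >= cp.n_patients:
        raise ValueError("patient_index out of range")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([cp.seed, patient_index]))
    n = cp.n_samples
    dt_hours = cp.trend_dt_s / 3600.0

    fluct: dict[str, np.ndarray] = {ch: np.zeros(n) for ch in TREND_CHANNELS}
    used: dict[str, float] = {ch: 0.0 for ch in TREND_CHANNELS}
    switch_times: dict[str, np.ndarray] = {}
    for pair in cp.coupling_pairs:
        z = rng.standard_normal(n)
        if pair.effect_span_hours is not None and at_risk:
            lo, hi = pair.effect_span_hours

            def rate_fn(h, lo=lo, hi=hi, pair=pair):
                return pair.rate_at_risk if lo <= h < hi else pair.rate_baseline
        else:
            rate = pair.rate_at_risk if (at_risk and pair.effect_span_hours is None) \
                else pair.rate_baseline

            def rate_fn(h, rate=rate):
                return rate
        signs, times = _switch_sign_process(n, dt_hours, rate_fn, rng)
        amp = np.sqrt(pair.coupling)
        fluct[pair.ans] += amp * z
        fluct[pair.hemo] += amp * signs * z
        used[pair.ans] += pair.coupling
        used[pair.hemo] += pair.coupling
        switch_times[f"{pair.ans}-{pair.hemo}"] = times

    channels: dict[str, UniformSeries] = {}
    for ch in TREND_CHANNELS:
        spec = cp.channel_baselines[ch]
        resid = np.sqrt(max(0.0, 1.0 - used[ch]))
        f = fluct[ch] + resid * rng.standard_normal(n)
        base = spec.loc + spec.between_sd * rng.standard_normal()
        values = base + spec.within_sd * f
        if ch == "prx":
            values = np.clip(values, -1.0, 1.0)
        units = {"abp": "mmHg", "hr": "bpm", "brs": "ms/mmHg",
                 "icp": "mmHg", "prx": "a.u."}[ch]
        channels[ch] = UniformSeries(ch, 0.0, cp.trend_dt_s, values, units)

    return TrendRecord(
        patient_id=f"P{patient_index:03d}",
        channels=channels,
        meta={
            "at_risk": bool(at_risk),
            "switch_times_hours": switch_times,
        },
    )


def gen_metadata(
    cohort_params: CohortParams, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Clinical metadata table with the configured group structure.

    One row per patient (first ``n_at_risk`` rows are the at-risk group,
    matching the patient indexing of :func:`gen_trend_record`).
    """
    cp = cohort_params
    md = cp.metadata
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cp.seed, 10_000]))
    rows = []
    for i in range(cp.n_patients):
        at_risk = i < cp.n_at_risk
        mu, sig = md.age.for_group(at_risk)
        age = float(rng.lognormal(mu, sig))
        female = rng.random() < md.female_rate.for_group(at_risk)[0]
        g_lo, g_hi = md.gcs_range.for_group(at_risk)
        gcs = int(rng.integers(int(g_lo), int(g_hi) + 1))
        i_lo, i_hi = md.iss_range.for_group(at_risk)
        iss = int(rng.integers(int(i_lo), int(i_hi) + 1))
        multi = rng.random() < md.multiorgan_rate.for_group(at_risk)[0]
        hb_loc, hb_sd = md.hb.for_group(at_risk)
        hb = float(rng.normal(hb_loc, hb_sd))
        w_mu, w_sig = md.wbc.for_group(at_risk)
        wbc = float(rng.lognormal(w_mu, w_sig))
        row = {
            "patient_id": f"P{i:03d}",
            "psh_risk": int(at_risk),
            "age": age,
            "sex_male": int(not female),
            "gcs_sum": gcs,
            "iss": iss,
            "trauma_multiorgan": int(multi),
            "hb": hb,
            "wbc": wbc,
        }
        for flag, stats in md.ct_rates.items():
            row[flag] = int(rng.random() < stats.for_group(at_risk)[0])
        rows.append(row)
    return pd.DataFrame(rows, columns=list(METADATA_COLUMNS))


def inject_gaps(
    record: TrendRecord,
    missing_spec: MissingSpec,
    rng: np.random.Generator | int | None = None,
) -> TrendRecord:
    """Punch missing runs into every channel per the spec; returns a copy."""
    if missing_spec.empty:
        return record.copy()
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)
    out = record.copy()
    n = out.n_samples
    for ch in TREND_CHANNELS:
        mask = np.zeros(n, dtype=bool)
        if missing_spec.gap_lengths:
            for length in missing_spec.gap_lengths:
                _place_gap(mask, int(length), rng)
        else:
            target = int(round(missing_spec.fraction * n))
            lo, hi = missing_spec.gap_length_range
            guard = 0
            while mask.sum() < target and guard < 10_000:
                length = int(rng.integers(lo, hi + 1))
                length = min(length, target - int(mask.sum()))
                if length <= 0:
                    break
                _place_gap(mask, length, rng)
                guard += 1
        out.channels[ch].values[mask] = np.nan
    out.meta["missing_fraction_requested"] = (
        missing_spec.fraction if missing_spec.fraction is not None else None)
    return out


def _place_gap(mask: np.ndarray, length: int, rng: np.random.Generator) -> None:
    """Place one run of ``length`` True values at a random free position."""
    n = mask.size
    for _ in range(200):
        start = int(rng.integers(0, max(1, n - length)))
        if not mask[start : start + length].any():
            mask[start : start + length] = True
            return
    # dense mask: give up silently; the fraction loop re-tries with new draws


def gen_cohort(
    cohort_params: CohortParams,
) -> tuple[pd.DataFrame, list[TrendRecord]]:
    """Metadata table plus trend records (with gaps) for the whole cohort."""
    cp = cohort_params
    metadata = gen_metadata(cp)
    records = []
    for i in range(cp.n_patients):
        at_risk = i < cp.n_at_risk
        rec = gen_trend_record(cp, i, at_risk)
        gap_rng = np.random.default_rng(np.random.SeedSequence([cp.seed, 20_000 + i]))
        rec = inject_gaps(rec, cp.missing, gap_rng)
        records.append(rec)
    return metadata, records
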