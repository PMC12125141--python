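import warnings

import numpy as np
import pytest

from pshrisk import synthetic
from pshrisk.io import UniformSeries, TrendRecord, TREND_CHANNELS

# sklearn 1.8 deprecation chatter from LogisticRegression(penalty=...)
warnings.filterwarnings("ignore", category=FutureWarning, module="sklearn")


def make_trend_record(values_by_channel=None, n=4320, dt=60.0,
                      patient_id="T000") -> TrendRecord:
    """Minimal valid trend record; channels default to distinct constants."""
    channels = {}
    for i, ch in enumerate(TREND_CHANNELS):
        if values_by_channel and ch in values_by_channel:
            vals = np.asarray(values_by_channel[ch], dtype=float)
        else:
            vals = np.full(n, 10.0 + i)
        channels[ch] = UniformSeries(ch, 0.0, dt, vals, "a.u.")
    return TrendRecord(patient_id=patient_id, channels=channels)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (metadata + gap-injected records)."""
    params = synthetic.CohortParams(seed=7)
    metadata, records = synthetic.gen_cohort(params)
    return params, metadata, records


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
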