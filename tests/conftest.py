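import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dyadsync as ds

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cfg() -> ds.SimConfig:
    return ds.SimConfig(n_participants=6, n_rounds=2, seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_cfg) -> ds.StudyBundle:
    return ds.simulate_study(small_cfg)


@pytest.fixture(scope="session")
def hr_bundle() -> ds.StudyBundle:
    cfg = ds.SimConfig(
        n_participants=6,
        n_rounds=2,
        conditions=("Gazing", "JLM", "Eyes Closed"),
        modalities=("hr",),
        seed=7,
    )
    return ds.simulate_study(cfg)


def make_series(values, rate_hz=25.0, modality="smile", **kw) -> ds.SignalSeries:
    return ds.SignalSeries(
        participant_id=kw.pop("participant_id", "p0"),
        round=kw.pop("round", 1),
        modality=modality,
        rate_hz=rate_hz,
        values=np.asarray(values, dtype=float),
        **kw,
    )
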