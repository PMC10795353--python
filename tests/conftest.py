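import numpy as np
import pytest

from audibci import decoder, io_formats, stimgen, synthdata


def make_session(
    seed,
    n_cal=8,
    n_test=0,
    fs=250.0,
    montage="vamp16",
    preset="healthy",
    **overrides,
):
    """Small synthetic session for unit tests (reduced rate/montage)."""
    plan = stimgen.generate_session(
        n_calibration=n_cal, n_test=n_test, seed=seed, montage_name=montage
    )
    factory = {
        "healthy": synthdata.healthy_config,
        "zero": synthdata.zero_effect_config,
    }[preset]
    cfg = factory(seed=seed, fs=fs, montage=montage, **overrides)
    rec = synthdata.simulate_session(plan, cfg)
    cal = [b.target for b in plan.calibration_blocks]
    test = [b.target for b in plan.test_blocks]
    return plan, rec, cal, test


@pytest.fixture(scope="session")
def small_session():
    """10-block 16-channel 250 Hz healthy session shared across tests."""
    return make_session(seed=7, n_cal=10)


@pytest.fixture(scope="session")
def small_model(small_session):
    _, rec, cal, _ = small_session
    cfg = io_formats.PipelineConfig(n_xdawn_filters=2)
    return decoder.fit(rec, cal, cfg), cfg


@pytest.fixture
def rng():
    return np.random.default_rng(0)
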