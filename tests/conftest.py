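import numpy as np
import pytest

from thetalock import gphase, preprocess, synth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sine_trace():
    """Pure 5 Hz unit-amplitude sinusoid, 20 s at 2 kHz."""
    fs = 2000.0
    t = np.arange(int(20 * fs)) / fs
    return preprocess.LfpTrace(samples=np.cos(2 * np.pi * 5.0 * t), fs=fs)


@pytest.fixture(scope="session")
def sine_phase(sine_trace):
    return gphase.generalized_phase(sine_trace)


@pytest.fixture(scope="session")
def small_session():
    """120 s session with one strongly locked unit and one Poisson unit."""
    units = [
        synth.UnitSpec(mode="locked", base_rate=2.5, kappa=4.0,
                       mu_encoding=np.pi, mu_retrieval=np.pi, wire=0),
        synth.UnitSpec(mode="poisson", base_rate=2.5, wire=0),
    ]
    cfg = synth.SynthConfig(duration_s=120.0, n_trials=4, units=units,
                            seed=7, burst_rate=10.0)
    return synth.gen_session(cfg)


@pytest.fixture(scope="session")
def small_cohort(small_session):
    from thetalock import pipeline

    return pipeline.process_session(small_session)
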