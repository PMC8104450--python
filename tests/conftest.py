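import numpy as np
import pytest

from thetaflex.neuron_models import build_model
from thetaflex.simulator import integrate


@pytest.fixture(scope="session")
def ms_tonic_trace():
    """6 s noisy tonic run of model MS, shared across tests."""
    return integrate(build_model("MS"), None, 6000.0, 0.01, seed=1,
                     record_stride=100)


@pytest.fixture(scope="session")
def m_noisefree_trace():
    """10 s noise-free tonic run of model M (gate-range invariant checks)."""
    cfg = build_model("M")
    cfg.p_noise = 0.0
    return integrate(cfg, None, 10000.0, 0.01, seed=0, record_stride=100)


@pytest.fixture(scope="session")
def mis_noisefree_trace():
    """10 s noise-free tonic run of model MIS (two-cell, all currents)."""
    cfg = build_model("MIS")
    cfg.p_noise = 0.0
    return integrate(cfg, None, 10000.0, 0.01, seed=0, record_stride=100)
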