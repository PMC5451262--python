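import numpy as np
import pytest

import iftsim as m


@pytest.fixture(scope="session")
def default_run():
    """One 60 s unperturbed IFT54 simulation shared across tests."""
    cfg = m.build_default_config(["IFT54"], duration=60.0, seed=11)
    log, trace = m.run_simulation(cfg)
    return cfg, log, trace


@pytest.fixture(scope="session")
def default_kymogram(default_run):
    cfg, log, trace = default_run
    rcfg = m.RenderConfig()
    kym = m.render_kymogram(trace, rcfg, np.random.default_rng(7))["IFT54"]
    return kym


@pytest.fixture(scope="session")
def noise_free_run():
    """Short noise-free render of a sparse-traffic cell, with ground truth."""
    cfg = m.build_default_config(["IFT54"], duration=30.0, seed=5,
                                 departure_rate=0.35, imaging_bleach_rate=0.0)
    log, trace = m.run_simulation(cfg)
    rcfg = m.RenderConfig(shot_noise=False, read_noise_sd=0.0)
    kym = m.render_kymogram(trace, rcfg, np.random.default_rng(0))["IFT54"]
    return cfg, log, trace, kym
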