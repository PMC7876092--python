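import dataclasses

import pytest

import vcnflow as vf


@pytest.fixture(scope="session")
def control_threshold():
    """Gate threshold from a large simulated non-transduced control.

    Session-scoped: the control is the anchor for every gated readout and is
    deterministic for its seed.
    """
    cfg = vf.SimConfig(n_cells=1_000_000, lam=0.0, seed=20_001)
    control = vf.simulate_flow_events(vf.simulate_copy_numbers(cfg), cfg, label="control")
    return vf.fit_threshold(control)


@pytest.fixture
def poisson_sample():
    """A λ=1 Poisson sample with events, at a size where gating error is tiny."""
    cfg = vf.SimConfig(n_cells=100_000, lam=1.0, seed=20_002)
    truth = vf.simulate_copy_numbers(cfg)
    events = vf.simulate_flow_events(truth, cfg, label="lam1")
    return cfg, truth, events
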