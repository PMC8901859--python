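import numpy as np
import pytest

import v1sense as v
from v1sense.protocol import StimulusProtocol


@pytest.fixture(scope="session")
def protocol() -> StimulusProtocol:
    return StimulusProtocol.generate(seed=7)


@pytest.fixture(scope="session")
def wt_session(protocol):
    """One wild-type-like stimulus session: population, truth, traces,
    events, response table (background transients off, so per-trial
    responses match the generator's Bernoulli draws)."""
    pop = v.make_uniform_population(50, seed=11)
    cfg = v.SimConfig(T=protocol.span, bg_rate=0.0)
    truth = v.simulate_activity(pop, protocol, cfg, seed=11)
    ts = v.render_traces(truth, cfg, positions=pop.positions, seed=11)
    ts = v.compute_dff(ts)
    events = v.detect_transients(ts)
    table = v.classify_responsive(events, protocol)
    return dict(pop=pop, cfg=cfg, truth=truth, traces=ts, events=events, table=table)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
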