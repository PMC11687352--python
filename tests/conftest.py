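import numpy as np
import pytest

import phytoforage as pf


@pytest.fixture(scope="session")
def high_landscape() -> pf.ToxinLandscape:
    """A clustered high-variation landscape shared across tests."""
    return pf.make_landscape(beta=5.0, variation="high", seed=7)


@pytest.fixture(scope="session")
def null_track(high_landscape) -> pf.Track:
    """A moderately long track from a preference-free agent."""
    cfg = pf.SimConfig(n_steps=400, seed=11)
    return pf.simulate_track(
        high_landscape, pf.AgentBehaviour(), cfg, rng=np.random.default_rng(11)
    )


@pytest.fixture(scope="session")
def arrested_track(high_landscape) -> pf.Track:
    """A 1200-step track with strong arrestment and immigration (a=4, w=1.25)."""
    cfg = pf.SimConfig(n_steps=1200, seed=13)
    beh = pf.AgentBehaviour(arrestment=4.0, immigration=1.25, size_class="large")
    return pf.simulate_track(
        high_landscape, beh, cfg, rng=np.random.default_rng(13)
    )
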