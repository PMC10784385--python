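import numpy as np
import pytest

import calyswe as c


@pytest.fixture(scope="session")
def tto_design():
    # few restarts keep the fixture fast; D-optimality level is irrelevant
    # for the behaviour under test
    return c.generate_tto_design(seed=1, n_restarts=3)


@pytest.fixture(scope="session")
def dce_design():
    return c.generate_dce_design(seed=1)


@pytest.fixture(scope="session")
def engaged_survey(tto_design, dce_design):
    """Small engaged-only synthetic survey (no careless participants)."""
    cfg = c.TrueValueConfig(n_participants=120, seed=5, careless_fraction=0.0)
    participants, tto, dce = c.simulate_survey(cfg, tto_design, dce_design)
    return {"config": cfg, "participants": participants, "tto": tto, "dce": dce}


@pytest.fixture(scope="session")
def mixed_survey(tto_design, dce_design):
    """Survey with the default 20% careless contamination."""
    cfg = c.TrueValueConfig(n_participants=150, seed=9, careless_fraction=0.2)
    participants, tto, dce = c.simulate_survey(cfg, tto_design, dce_design)
    return {"config": cfg, "participants": participants, "tto": tto, "dce": dce}
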