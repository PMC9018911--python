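import numpy as np
import pytest

from commcouple.predictors import build_battery
from commcouple.synthetic import (
    SyntheticConfig,
    fixture_graphs,
    generate_fc,
    generate_geometry,
    generate_sc,
)


@pytest.fixture(scope="session")
def fixtures():
    """Named tiny graphs with geometry used by the oracle tests."""
    return fixture_graphs()


@pytest.fixture(scope="session")
def subject():
    """One medium synthetic subject: geometry, SC, predictor stack, FC and
    the planted ground truth (noise_sd = 0.1)."""
    cfg = SyntheticConfig(n_nodes=60, n_systems=6, density=0.2)
    geo = generate_geometry(cfg, seed=11)
    sc = generate_sc(geo, cfg, seed=12)
    stack = build_battery(sc, geo)
    fc, truth = generate_fc(sc, geo, cfg, seed=13, stack=stack)
    return {"config": cfg, "geometry": geo, "sc": sc, "stack": stack,
            "fc": fc, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
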