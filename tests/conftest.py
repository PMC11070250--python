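import numpy as np
import pandas as pd
import pytest

from ednascape.network import RiverNetwork, generate_synthetic_network
from ednascape.synthetic import make_scenario, ScenarioConfig


def chain_network(lengths, velocities, widths=None, local=None,
                  discharge=None) -> RiverNetwork:
    """Linear chain a->b->c->... with the last reach as outlet."""
    n = len(lengths)
    ids = [chr(ord("a") + k) for k in range(n)]
    down = [ids[k + 1] for k in range(n - 1)] + [None]
    widths = widths if widths is not None else np.ones(n)
    local = local if local is not None else np.ones(n)
    # discharge must grow downstream; chain order is upstream->downstream
    discharge = discharge if discharge is not None else np.arange(1, n + 1, dtype=float)
    return RiverNetwork(ids, down, np.asarray(lengths, float), widths,
                        local, discharge, np.asarray(velocities, float))


@pytest.fixture
def chain3() -> RiverNetwork:
    return chain_network([100.0, 100.0, 200.0], [1.0, 1.0, 2.0])


@pytest.fixture
def net200() -> RiverNetwork:
    return generate_synthetic_network(200, seed=42)


@pytest.fixture(scope="session")
def default_scenario():
    return make_scenario(ScenarioConfig(), seed=1)
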