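import numpy as np
import pandas as pd
import pytest

from protrusim import SimulationConfig, build_row
from protrusim.signaling import DifferentiationRule, SignalParams


@pytest.fixture
def uniform_row():
    """Ten cells of exactly 10 um: edges at 0, 10, ..., centers at 5, 15, ..."""
    return build_row(10, diameter_mean=10.0, diameter_sd=0.0, seed=0)


@pytest.fixture
def small_row():
    return build_row(5, diameter_mean=11.10, diameter_sd=4.51, seed=42)


@pytest.fixture
def fast_config():
    """A config whose replicates finish in a few thousand steps."""
    return SimulationConfig(
        n_cells=20,
        n_replicates=3,
        seed=0,
        rule=DifferentiationRule(p=0.05, N_th=0.2, q=6.0),
    )


def make_events(records):
    """Event table from (stretch_id, position, time) triples."""
    frame = pd.DataFrame(records, columns=["stretch_id", "position_um", "time"])
    frame["cell_id"] = np.arange(len(frame))
    frame["genotype"] = "toy"
    frame["pair_id"] = pd.array([pd.NA] * len(frame))
    return frame


@pytest.fixture
def toy_events():
    return make_events
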