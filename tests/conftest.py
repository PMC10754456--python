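import numpy as np
import pandas as pd
import pytest

from clonalclock import signatures, sim


@pytest.fixture(scope="session")
def catalog2():
    """Two-signature synthetic catalog (clock-like peaked + broad)."""
    return signatures.synthetic_catalog()[["SBS1", "SBS5"]]


@pytest.fixture(scope="session")
def small_expansion():
    """A small seeded clonal expansion with its truth ledger."""
    cfg = sim.SimulationConfig(mu=0.5, omega=0.4, gamma=0.9, n0=3,
                               n_generations=10, seed=11)
    return sim.simulate_clonal_expansion(cfg)


@pytest.fixture()
def toy_variants():
    """Five hand-enumerated records for filter tests."""
    return pd.DataFrame({
        "chrom": ["c1"] * 5,
        "pos": [100, 200, 300, 400, 500],
        "ref": ["A", "C", "G", "T", "A"],
        "alt": ["G", "T", "A", "C", "T"],
        "qual": [40.0, 40.0, 30.0, 40.0, 40.0],
        "depth": [60, 20, 60, 60, 250],
        "alt_depth": [5, 5, 5, 2, 5],
    }).assign(f=lambda d: d.alt_depth / d.depth)
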