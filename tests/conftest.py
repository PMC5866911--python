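import numpy as np
import pandas as pd
import pytest

from heatgwas.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def small_sim():
    """One small synthetic study shared across read-only tests."""
    cfg = SimConfig(n_animals=240, n_snps=400, n_qtl=8, target_h2=0.25, seed=7)
    return simulate_all(cfg)


@pytest.fixture
def toy_z():
    """Hand-built per-category z-values for four animals, all four categories."""
    rows = []
    vals = {
        "a1": {"Normal": 1.0, "Alert": -0.5, "Danger": 0.2, "Emergency": -1.0},
        "a2": {"Normal": -1.0, "Alert": 0.5, "Danger": -0.2, "Emergency": 1.0},
        "a3": {"Normal": 0.5, "Alert": 1.0, "Danger": -1.2, "Emergency": 0.3},
        "a4": {"Normal": -0.5, "Alert": -1.0, "Danger": 1.2, "Emergency": -0.3},
    }
    for a, cats in vals.items():
        for c, z in cats.items():
            rows.append({"animal_id": a, "category": c, "z": z})
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
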