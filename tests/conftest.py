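import numpy as np
import pandas as pd
import pytest

import twinclpm as t
from twinclpm.data import Schema


@pytest.fixture(scope="session")
def small_table():
    """50-pair complete teds-like panel with covariate effects."""
    cfg = t.SimulationConfig.from_dict(
        {**t.regime_presets("teds_like", n_pairs=50).to_dict(),
         "missing_rate": 0.0})
    return t.attach_covariates(t.simulate_twin_panel(cfg, seed=7), cfg)


@pytest.fixture(scope="session")
def medium_table():
    """1000-pair complete panel with a known cross-lag (bp -> mp = 0.3)."""
    cfg = t.regime_presets("true_crosslag", n_pairs=1000)
    return t.simulate_twin_panel(cfg, seed=11)


@pytest.fixture()
def three_pair_csv(tmp_path):
    """Minimal hand-written 3-pair file in the default schema."""
    cols = Schema().value_columns()
    rows = []
    for i in range(3):
        rows.append([f"p{i}", float(i % 2), 9.1, 12.0, 15.9]
                    + [float(i + k % 5) for k in range(len(cols))])
    frame = pd.DataFrame(rows, columns=["pair_id", "sex", "age9", "age12",
                                        "age16"] + cols)
    path = tmp_path / "three_pairs.csv"
    frame.to_csv(path, index=False)
    return path, frame
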