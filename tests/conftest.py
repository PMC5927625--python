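import numpy as np
import pandas as pd
import pytest

import memascreen as ms


@pytest.fixture(scope="session")
def small_design():
    """One-cell-line canned design: 6 ECM x 8 ligands, 20 arrays."""
    return ms.fixture_design(7, cell_lines=("AU565",))


@pytest.fixture(scope="session")
def small_params():
    return ms.fixture_params(7)


@pytest.fixture(scope="session")
def small_cells(small_design, small_params):
    return ms.simulate_experiment(small_design, small_params)


@pytest.fixture(scope="session")
def small_spots(small_design, small_cells):
    """Filtered, gated, spot-summarized table for the canned experiment."""
    kept, excluded = ms.filter_nuclei(small_cells)
    gated, _ = ms.gate_edu(kept)
    return ms.summarize_spots(gated, small_design, excluded)


def make_mixture_cells(seed, n=5000, pos_frac=0.30, mu_neg=2.0, mu_pos=4.0, sd=0.4):
    """Single-array cell table with a two-component log-normal EdU mixture."""
    rng = np.random.default_rng(seed)
    pos = rng.random(n) < pos_frac
    logint = np.where(pos, rng.normal(mu_pos, sd, n), rng.normal(mu_neg, sd, n))
    return pd.DataFrame({
        "array_id": "a1", "spot_row": 0, "spot_col": 0, "cell_id": np.arange(n),
        "edu_mean_intensity": np.exp(logint), "edu_true_label": pos,
    })
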