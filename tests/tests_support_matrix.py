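"""Shared helper for constructing SignalMatrix test instances."""

import numpy as np
import pandas as pd

from memascreen.normalize import SignalMatrix


def grid_matrix(values, ecm_groups, n_cols=10):
    """Wrap a 2-D array as a SignalMatrix with the given per-column ECM labels."""
    n_arr, n_spot = np.asarray(values).shape
    cm = pd.DataFrame({"spot_row": np.arange(n_spot) // n_cols,
                       "spot_col": np.arange(n_spot) % n_cols,
                       "ecm": ecm_groups})
    rm = pd.DataFrame({"array_id": [f"a{i:03d}" for i in range(n_arr)],
                       "cell_line": "CL", "treatment": "T", "ligand": "L"})
    return SignalMatrix("x", np.asarray(values, float), rm, cm)
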