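"""Per-cell to per-spot reduction: nuclei filtering, EdU auto-gating, medians.

The spot cell count is the number of DAPI-segmented nuclei surviving the size
gate; proliferation is the fraction of nuclei called EdU-positive by a
data-driven threshold on log EdU intensity; stain intensities and nuclear
morphology are median-summarized per spot.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm
from skimage.filters import threshold_otsu
from sklearn.mixture import GaussianMixture

from .design import ArrayDesign
from .errors import SpotKeyError

SPOT_KEY = ["array_id", "spot_row", "spot_col"]

SPOT_COLUMNS = [
    "array_id", "spot_row", "spot_col", "ecm", "ligand", "treatment", "cell_line",
    "cell_count", "edu_fraction", "krt14_median", "krt19_median",
    "nuclear_area_median", "n_excluded",
]

#: Default relative size gate: keep nuclei within [0.3, 3.0] x the per-array
#: median area.  Scale-free, so it transfers across magnifications.
DEFAULT_REL_GATE = (0.3, 3.0)


def filter_nuclei(
    cells: pd.DataFrame,
    min_area: float | None = None,
    max_area: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Size-gate nuclei to exclude apoptotic (and unsegmentable) objects.

    With explicit bounds, keeps rows with ``min_area <= nuclear_area <=
    max_area``.  With bounds omitted, applies the relative default gate of
    ``DEFAULT_REL_GATE`` times the per-array median area.

    Returns ``(kept, excluded)``; excluded rows feed the per-spot
    ``n_excluded`` bookkeeping in :func:`summarize_spots`.
    """
    if min_area is not None and max_area is not None and min_area >= max_area:
        raise ValueError("min_area must be below max_area")
    if cells.empty:
        return cells.copy(), cells.copy()
    area = cells["nuclear_area"]
    if min_area is None or max_area is None:
        med = cells.groupby("array_id")["nuclear_area"].transform("median")
        lo = med * DEFAULT_REL_GATE[0] if min_area is None else min_area
        hi = med * DEFAULT_REL_GATE[1] if max_area is None else max_area
    else:
        lo, hi = min_area, max_area
    keep = (area >= lo) & (area <= hi)
    return cells[keep].copy(), cells[~keep].copy()


def _mixture_threshold(log_int: np.ndarray) -> tuple[float, str, bool]:
    """Threshold on log intensity: 2-component Gaussian mixture cut at equal
    posterior, falling back to Otsu when the fit is degenerate.

    Returns (threshold, method, flagged).
    """
    if np.ptp(log_int) < 1e-12:
        # no separable components: call everything negative
        return np.inf, "constant", True
    q25, q75 = np.quantile(log_int, [0.25, 0.75])
    gm = GaussianMixture(
        n_components=2, covariance_type="full", random_state=0,
        means_init=np.array([[q25], [q75]]))
    gm.fit(log_int.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    lo, hi = np.argsort(means)
    degenerate = (weights.min() < 0.01
                  or abs(means[hi] - means[lo]) < 0.5 * sds.mean())
    if not degenerate:
        def post_diff(x):
            return (np.log(weights[hi]) + norm.logpdf(x, means[hi], sds[hi])
                    - np.log(weights[lo]) - norm.logpdf(x, means[lo], sds[lo]))
        a, b = means[lo], means[hi]
        if post_diff(a) < 0 < post_diff(b):
            return float(brentq(post_diff, a, b)), "gmm", False
        degenerate = True
    return float(threshold_otsu(log_int)), "otsu", True


def gate_edu(
    cells: pd.DataFrame,
    scope: str = "array_id",
    min_group: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Auto-gate per-cell EdU intensity into EdU+/EdU- labels.

    The threshold is estimated per ``scope`` group (default per array, since
    staining intensity drifts between arrays); groups smaller than
    ``min_group`` cells borrow the global threshold fit on all cells.

    Returns ``(cells with an added boolean 'edu_pos' column, report)`` where
    the report has one row per group: n_cells, method, threshold (on the log
    intensity scale) and a flag for degenerate or fallback fits.
    """
    out = cells.copy()
    if out.empty:
        out["edu_pos"] = pd.Series(dtype=bool)
        report = pd.DataFrame(columns=["group", "n_cells", "method", "threshold", "flagged"])
        return out, report
    log_int = np.log(out["edu_mean_intensity"].to_numpy(float))
    global_thr, global_method, global_flag = _mixture_threshold(log_int)
    rows = []
    edu_pos = np.zeros(len(out), dtype=bool)
    for group, idx in out.groupby(scope, sort=True).indices.items():
        vals = log_int[idx]
        if len(vals) < min_group:
            thr, method, flagged = global_thr, f"global_{global_method}", True
        else:
            thr, method, flagged = _mixture_threshold(vals)
        edu_pos[idx] = vals > thr
        rows.append((group, len(vals), method, thr, flagged))
    out["edu_pos"] = edu_pos
    report = pd.DataFrame(rows, columns=["group", "n_cells", "method", "threshold", "flagged"])
    return out, report


def summarize_spots(
    cells: pd.DataFrame,
    design: ArrayDesign,
    excluded: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Reduce gated cells to one row per printed spot of the design.

    ``cells`` must already be size-filtered and carry the ``edu_pos`` gate
    column.  Spots with no surviving cells are emitted with ``cell_count`` 0
    and NaN summaries so replicate bookkeeping stays aligned with the design.
    ``excluded`` (the second return of :func:`filter_nuclei`) fills the
    per-spot ``n_excluded`` audit column.
    """
    if not cells.empty and "edu_pos" not in cells.columns:
        raise ValueError("cells must be gated first (missing 'edu_pos'); run gate_edu")
    manifest = design.to_manifest()
    man_keys = pd.MultiIndex.from_frame(manifest[SPOT_KEY])
    for name, tab in (("cells", cells), ("excluded", excluded)):
        if tab is None or tab.empty:
            continue
        keys = pd.MultiIndex.from_frame(tab[SPOT_KEY].drop_duplicates())
        unknown = keys.difference(man_keys)
        if len(unknown):
            raise SpotKeyError(
                f"{name} table references {len(unknown)} spot keys absent from the design, "
                f"e.g. {list(unknown[:5])}")

    if cells.empty:
        agg = pd.DataFrame(columns=SPOT_KEY + [
            "cell_count", "edu_fraction", "krt14_median", "krt19_median", "nuclear_area_median"])
    else:
        g = cells.groupby(SPOT_KEY, sort=False)
        agg = g.agg(
            cell_count=("cell_id", "size"),
            edu_fraction=("edu_pos", "mean"),
            krt14_median=("krt14_intensity", "median"),
            krt19_median=("krt19_intensity", "median"),
            nuclear_area_median=("nuclear_area", "median"),
        ).reset_index()
    spots = manifest.merge(agg, on=SPOT_KEY, how="left")
    spots["cell_count"] = spots["cell_count"].fillna(0).astype(int)
    if excluded is not None and not excluded.empty:
        exc = excluded.groupby(SPOT_KEY).size().rename("n_excluded").reset_index()
        spots = spots.merge(exc, on=SPOT_KEY, how="left")
        spots["n_excluded"] = spots["n_excluded"].fillna(0).astype(int)
    else:
        spots["n_excluded"] = 0
    return spots[SPOT_COLUMNS]
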