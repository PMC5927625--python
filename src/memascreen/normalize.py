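"""Two-stage MEMA normalization: RUV with replicate-median-residual controls,
then bivariate LOESS over the spot grid, applied independently per signal.

Each signal (cell count, EdU+ fraction, stain medians, morphology medians) is
arranged as one matrix with arrays as rows and printed spot positions as
columns; the shared print layout makes the columns align across arrays.

RUV (removing unwanted variation) uses negative controls that are available
for free on a spotted array: within each array, replicate spots of the same
ECM should measure the same biology, so their deviations from the per-(array,
ECM) replicate median are purely technical.  The rank-k truncated SVD of that
residual matrix estimates the dominant technical patterns, and subtracting it
from the data removes them.  Note what this construction can and cannot see:
a nuisance constant across all spots of an array has zero replicate residual
and is deliberately preserved (array level is biology: the ligand lives at
the array level).

Bivariate LOESS then removes the smooth spatial artifact that remains within
each array: a local-polynomial regression of the value on (spot_row,
spot_col) with tricube distance weights over the nearest span-fraction of
spots is fitted per array and subtracted, and the array's pre-fit median is
added back so the array's level is untouched.

All fits operate on variance-stabilizing transforms (log2(count+1), logit for
fractions, log2 for intensities) and results are mapped back to the original
scale on write-out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import LayoutError, NumericalError
from .spots import SPOT_KEY

DEFAULT_SIGNALS = ["cell_count", "edu_fraction", "krt14_median",
                   "krt19_median", "nuclear_area_median"]

DEFAULT_TRANSFORMS = {
    "cell_count": "log2p1",
    "edu_fraction": "logit",
    "krt14_median": "log2",
    "krt19_median": "log2",
    "nuclear_area_median": "log2",
}

ROW_META = ["array_id", "cell_line", "treatment", "ligand"]
COL_META = ["spot_row", "spot_col", "ecm"]


@dataclass
class SignalMatrix:
    """One signal arranged arrays x spots, aligned to design metadata."""

    signal_name: str
    values: np.ndarray  # (n_arrays, n_spots) float
    row_meta: pd.DataFrame  # per-array annotations (ROW_META columns)
    col_meta: pd.DataFrame  # per-spot-position annotations (COL_META columns)
    transform: str = "identity"
    transform_eps: float = 0.0  # logit clamp, recorded for exact inversion

    def copy(self) -> "SignalMatrix":
        return SignalMatrix(self.signal_name, self.values.copy(),
                            self.row_meta.copy(), self.col_meta.copy(),
                            self.transform, self.transform_eps)


@dataclass
class NormalizationModel:
    """Fitted normalization state for one signal (deterministic, seed-free)."""

    signal_name: str
    k_unwanted: int = 0
    loess_span: float | None = None
    loess_degree: int = 1
    singular_values: np.ndarray | None = None
    removed_component: np.ndarray | None = field(default=None, repr=False)
    surfaces: np.ndarray | None = field(default=None, repr=False)
    single_replicate_spots: int = 0


# --- transforms --------------------------------------------------------------

def apply_transform(x: np.ndarray, transform: str, eps: float = 0.0) -> np.ndarray:
    if transform == "identity":
        return x.copy()
    if transform == "log2p1":
        return np.log2(x + 1.0)
    if transform == "log2":
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(x > 0, np.log2(np.where(x > 0, x, 1.0)), np.nan)
    if transform == "logit":
        p = np.clip(x, eps, 1.0 - eps)
        return np.log(p / (1.0 - p))
    raise NumericalError(f"unknown transform {transform!r}")


def invert_transform(y: np.ndarray, transform: str, eps: float = 0.0) -> np.ndarray:
    if transform == "identity":
        return y.copy()
    if transform == "log2p1":
        return np.clip(np.exp2(y) - 1.0, 0.0, None)
    if transform == "log2":
        return np.exp2(y)
    if transform == "logit":
        return 1.0 / (1.0 + np.exp(-y))
    raise NumericalError(f"unknown transform {transform!r}")


def build_signal_matrix(spots: pd.DataFrame, signal: str,
                        transform: str | None = None) -> SignalMatrix:
    """Pivot one spot-level signal into an arrays x spots matrix.

    Requires the same printed layout (coordinate set and ECM assignment) on
    every array. NaNs in the signal are preserved.
    """
    if signal not in spots.columns:
        raise NumericalError(f"signal column {signal!r} not in spot table")
    if transform is None:
        transform = DEFAULT_TRANSFORMS.get(signal, "identity")

    layouts = spots.groupby("array_id", sort=True)
    ref = None
    for _, sub in layouts:
        lay = sub.sort_values(["spot_row", "spot_col"])[COL_META].reset_index(drop=True)
        if ref is None:
            ref = lay
        elif not lay.equals(ref):
            raise LayoutError("arrays do not share one printed layout; cannot align columns")

    wide = spots.pivot(index="array_id", columns=["spot_row", "spot_col"], values=signal)
    wide = wide.sort_index(axis=0).sort_index(axis=1)
    col_meta = pd.DataFrame(
        [(r, c) for r, c in wide.columns], columns=["spot_row", "spot_col"])
    col_meta = col_meta.merge(ref, on=["spot_row", "spot_col"], how="left")
    row_meta = (spots[ROW_META].drop_duplicates("array_id")
                .sort_values("array_id").reset_index(drop=True))

    eps = 0.0
    if transform == "logit":
        max_count = spots["cell_count"].max()
        eps = 1.0 / (2.0 * max(float(max_count), 1.0))
    values = apply_transform(wide.to_numpy(float), transform, eps)
    return SignalMatrix(signal, values, row_meta, col_meta, transform, eps)


# --- RUV ---------------------------------------------------------------------

def replicate_median_residuals(m: SignalMatrix) -> np.ndarray:
    """Residuals of each spot from its within-array ECM replicate median.

    These are the RUV negative controls: same shape as ``m.values``, NaN-safe
    (NaNs are skipped in medians and propagate through). An ECM with a single
    spot in an array contributes a residual of exactly 0 (it is its own
    median); such spots are counted and reported via a warning.
    """
    values = m.values
    res = np.full_like(values, np.nan)
    singles = 0
    group_cols = m.col_meta.groupby("ecm", sort=True).indices
    any_replicated = False
    for ecm, idx in group_cols.items():
        sub = values[:, idx]
        if len(idx) == 1:
            singles += values.shape[0]
            res[:, idx] = np.where(np.isnan(sub), np.nan, 0.0)
            continue
        any_replicated = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            med = np.nanmedian(sub, axis=1, keepdims=True)
        res[:, idx] = sub - med
    if not any_replicated:
        raise NumericalError("no ECM has >= 2 replicate spots; residual controls undefined")
    if singles:
        warnings.warn(f"{singles} single-replicate spot values have residual fixed at 0",
                      stacklevel=2)
    return res


def ruv_normalize(m: SignalMatrix, k: int = 3) -> tuple[SignalMatrix, NormalizationModel]:
    """Remove the rank-``k`` technical component estimated from replicate residuals.

    ``k = 0`` returns the matrix unchanged (but still reports the singular
    value scree so users can choose ``k``). The SVD sign convention is fixed
    (largest-magnitude spot loading positive per component), making the
    decomposition — hence the whole pipeline — deterministic.
    """
    n, p = m.values.shape
    if k < 0 or k > min(n, p):
        raise NumericalError(f"k={k} outside [0, min(dims)={min(n, p)}]")
    R = replicate_median_residuals(m)
    R0 = np.nan_to_num(R, nan=0.0)
    U, s, Vt = np.linalg.svd(R0, full_matrices=False)
    # fix signs: per component, the largest-|loading| entry of v is positive
    for i in range(len(s)):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    model = NormalizationModel(signal_name=m.signal_name, k_unwanted=k,
                               singular_values=s.copy())
    out = m.copy()
    if k == 0:
        return out, model
    tol = max(n, p) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    achievable = int(np.sum(s > tol))
    if k > achievable:
        raise NumericalError(
            f"k={k} exceeds the residual matrix's achievable rank {achievable}")
    Rk = (U[:, :k] * s[:k]) @ Vt[:k]
    out.values = m.values - Rk  # NaN positions stay NaN
    model.removed_component = Rk
    return out, model


# --- bivariate LOESS ---------------------------------------------------------

def _loess2d(coords_fit: np.ndarray, y_fit: np.ndarray, coords_pred: np.ndarray,
             span: float, degree: int) -> np.ndarray:
    """Local-polynomial surface: tricube weights over the nearest span-fraction."""
    n = len(y_fit)
    k = min(n, int(np.ceil(span * n)))
    D = cdist(coords_pred, coords_fit)
    preds = np.empty(len(coords_pred))
    for i in range(len(coords_pred)):
        idx = np.argpartition(D[i], k - 1)[:k] if k < n else np.arange(n)
        d = D[i, idx]
        dmax = d.max()
        w = (1.0 - (d / dmax) ** 3) ** 3 if dmax > 0 else np.ones_like(d)
        dr = coords_fit[idx, 0] - coords_pred[i, 0]
        dc = coords_fit[idx, 1] - coords_pred[i, 1]
        if degree == 1:
            X = np.column_stack([np.ones(len(idx)), dr, dc])
        else:
            X = np.column_stack([np.ones(len(idx)), dr, dc, dr * dr, dr * dc, dc * dc])
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y_fit[idx] * sw, rcond=None)
        preds[i] = beta[0]  # local model is centered at the prediction point
    return preds


def loess_spatial_normalize(
    m: SignalMatrix, span: float = 0.5, degree: int = 2,
) -> tuple[SignalMatrix, NormalizationModel]:
    """Subtract a per-array smooth spatial surface fitted on (spot_row, spot_col).

    The array's pre-fit median is added back, so the correction changes only
    the within-array spatial pattern, never the array's level. Deterministic.
    """
    if not 0 < span <= 1:
        raise NumericalError(f"span must be in (0, 1], got {span}")
    if degree not in (1, 2):
        raise NumericalError("degree must be 1 or 2")
    coords = m.col_meta[["spot_row", "spot_col"]].to_numpy(float)
    out = m.copy()
    surfaces = np.full_like(m.values, np.nan)
    for i in range(m.values.shape[0]):
        row = m.values[i]
        finite = np.isfinite(row)
        n_fin = int(finite.sum())
        if n_fin == 0:
            continue
        k = int(np.ceil(span * n_fin))
        if k < 6:
            raise NumericalError(
                f"span {span} leaves {k} < 6 points per local fit on array "
                f"{m.row_meta['array_id'].iloc[i]}; minimal feasible span is {6.0 / n_fin:.4f}")
        fitted = _loess2d(coords[finite], row[finite], coords[finite], span, degree)
        med = np.median(row[finite])
        out.values[i, finite] = row[finite] - fitted + med
        surfaces[i, finite] = fitted - med
    model = NormalizationModel(signal_name=m.signal_name, loess_span=span,
                               loess_degree=degree, surfaces=surfaces)
    return out, model


# --- full per-signal pipeline ------------------------------------------------

def normalize_pipeline(
    spots: pd.DataFrame,
    signals: list[str] | None = None,
    k: int = 3,
    span: float = 0.5,
    degree: int = 2,
) -> tuple[pd.DataFrame, dict[str, list[NormalizationModel]]]:
    """Normalize each signal independently: matrix -> RUV(k) -> LOESS(span).

    Returns the spot table with each listed signal replaced by its normalized,
    back-transformed value (the raw value is preserved in ``<signal>_raw``),
    plus the fitted models keyed by signal.
    """
    if signals is None:
        signals = [s for s in DEFAULT_SIGNALS if s in spots.columns]
    out = spots.copy()
    models: dict[str, list[NormalizationModel]] = {}
    for signal in signals:
        try:
            m = build_signal_matrix(spots, signal)
            m_ruv, ruv_model = ruv_normalize(m, k)
            m_fin, loess_model = loess_spatial_normalize(m_ruv, span, degree)
        except NumericalError as e:
            raise NumericalError(f"signal {signal!r}: {e}") from e
        models[signal] = [ruv_model, loess_model]
        back = invert_transform(m_fin.values, m_fin.transform, m_fin.transform_eps)
        long = pd.DataFrame(back, index=m_fin.row_meta["array_id"])
        long.columns = pd.MultiIndex.from_frame(m_fin.col_meta[["spot_row", "spot_col"]])
        long = long.stack(list(range(2)), future_stack=True).rename(signal).reset_index()
        out = out.rename(columns={signal: f"{signal}_raw"}).merge(
            long, on=SPOT_KEY, how="left")
    return out[[c for c in out.columns]], models


def scree_table(models: dict[str, list[NormalizationModel]]) -> pd.DataFrame:
    """Singular-value scree of the residual matrices, one row per component."""
    rows = []
    for signal, mods in models.items():
        for mod in mods:
            if mod.singular_values is None:
                continue
            for i, s in enumerate(mod.singular_values, start=1):
                rows.append((signal, i, float(s), i <= mod.k_unwanted))
    return pd.DataFrame(rows, columns=["signal", "component", "singular_value", "removed"])
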