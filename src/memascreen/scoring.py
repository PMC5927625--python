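"""MEP-level summarization and drug-response attenuation scoring.

A MEP (microenvironment perturbagen) is one (ECM, ligand) pair. After
normalization, the ~15 replicate spots of each MEP are median-summarized, and
ligands/ECMs are scored for their ability to attenuate drug response:

* ``response_ratio``: treated / vehicle-control statistic per MEP (1 = no
  drug effect);
* ``rescue_score``: S(l) = (T_l - T_ref) / (C_ref - T_ref) with T the
  drug-arm and C the vehicle-arm median and ref the control ligand.  S = 0
  means the ligand behaves like the control under drug (no rescue), S = 1
  means full restoration to the vehicle-control level, S > 1 means
  stimulation beyond it.  This is a derived metric quantifying what hit
  calling reads off a count-vs-proliferation scatter.
* ``ecm_modifier_rank``: within one ligand and arm, ranks ECMs by their MEP
  median to expose matrix proteins that enhance or diminish the effect.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NumericalError

MEP_KEY = ["cell_line", "treatment", "ecm", "ligand"]

METRIC_COLUMNS = {
    "cell_count": ("median_cell_count", "sem_cell_count"),
    "edu_fraction": ("median_edu_fraction", "sem_edu_fraction"),
}


def summarize_mep(spots: pd.DataFrame) -> pd.DataFrame:
    """Median/SEM/n per (cell_line, treatment, ecm, ligand) over replicate spots.

    Spots with zero retained cells carry no measurement and are excluded from
    the medians; a MEP whose spots are all empty is reported with n = 0 and
    NaN summaries. SEM is the sample SD over contributing spots / sqrt(n).
    """
    df = spots.copy()
    empty = df["cell_count"] == 0
    for col in ["cell_count", "edu_fraction"]:
        df[col] = df[col].astype(float).where(~empty)
    g = df.groupby(MEP_KEY, sort=True)
    out = g.agg(
        median_cell_count=("cell_count", "median"),
        median_edu_fraction=("edu_fraction", "median"),
        sd_cc=("cell_count", "std"),
        sd_ef=("edu_fraction", "std"),
        n_replicates=("cell_count", "count"),
        n_ef=("edu_fraction", "count"),
    ).reset_index()
    out["sem_cell_count"] = out["sd_cc"] / np.sqrt(out["n_replicates"].where(out["n_replicates"] > 0))
    out["sem_edu_fraction"] = out["sd_ef"] / np.sqrt(out["n_ef"].where(out["n_ef"] > 0))
    return out[MEP_KEY + ["median_cell_count", "median_edu_fraction",
                          "sem_cell_count", "sem_edu_fraction", "n_replicates"]]


def response_ratio(treated: pd.DataFrame, control: pd.DataFrame,
                   metric: str = "cell_count") -> pd.DataFrame:
    """Per-MEP treated / control ratio of a summary statistic.

    ``treated`` and ``control`` are MEP summaries of the two arms; keys are
    matched on (cell_line, ecm, ligand). A zero control statistic yields NaN
    (with a warning), never +/-inf.
    """
    col = METRIC_COLUMNS[metric][0]
    key = ["cell_line", "ecm", "ligand"]
    merged = treated[key + [col]].merge(
        control[key + [col]], on=key, suffixes=("_treated", "_control"))
    denom = merged[f"{col}_control"]
    zero = denom == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} MEPs have a zero control statistic; ratio set to NaN",
                      stacklevel=2)
    merged["ratio"] = np.where(zero, np.nan,
                               merged[f"{col}_treated"] / denom.where(~zero))
    return merged


def rescue_score(
    summary: pd.DataFrame,
    reference_ligand: str = "PBS",
    treatment: str = "lapatinib",
    control_treatment: str = "DMSO",
    metric: str = "cell_count",
) -> pd.DataFrame:
    """Ligand-level rescue scores S(l) = (T_l - T_ref) / (C_ref - T_ref).

    T_l is the drug-arm median over all ECM spots of ligand l; C/T_ref are
    the vehicle/drug medians of the reference (control) ligand.  ``summary``
    may be either a (normalized) spot table — medians then pool every
    non-empty spot of the ligand, the preferred estimator — or a MEP summary,
    in which case the median is taken over the ECM-level MEP medians.
    Scored per cell line; ligands ranked by S descending (dense ranks).

    Raises :class:`NumericalError` when C_ref <= T_ref (no measurable drug
    effect on the reference, so rescue is undefined).
    """
    if metric in summary.columns:  # spot-level table: pool all ECM spots directly
        col = metric
        data = summary[summary["cell_count"] > 0]
    else:  # MEP summary: median over the ECM-level medians
        col = METRIC_COLUMNS[metric][0]
        data = summary
    frames = []
    for cl, sub in data.groupby("cell_line", sort=True):
        t_arm = sub[sub["treatment"] == treatment]
        c_arm = sub[sub["treatment"] == control_treatment]
        t_med = t_arm.groupby("ligand")[col].median()
        c_med = c_arm.groupby("ligand")[col].median()
        if reference_ligand not in t_med.index or reference_ligand not in c_med.index:
            raise NumericalError(
                f"reference ligand {reference_ligand!r} missing from an arm of {cl}")
        t_ref, c_ref = t_med[reference_ligand], c_med[reference_ligand]
        if not c_ref > t_ref:
            raise NumericalError(
                f"no drug effect on reference ligand in {cl}: vehicle median {c_ref:.4g} "
                f"<= drug median {t_ref:.4g}; rescue scores undefined")
        df = pd.DataFrame({
            "cell_line": cl,
            "ligand": t_med.index,
            "rescue_score": (t_med - t_ref) / (c_ref - t_ref),
            "treated_median": t_med,
            "control_median": c_med.reindex(t_med.index),
            "ref_treated_median": t_ref,
            "ref_control_median": c_ref,
        }).reset_index(drop=True)
        df["rank"] = df["rescue_score"].rank(method="dense", ascending=False).astype(int)
        frames.append(df.sort_values(["rank", "ligand"], ignore_index=True))
    return pd.concat(frames, ignore_index=True)


def ecm_modifier_rank(
    summary: pd.DataFrame,
    ligand: str,
    treatment: str = "lapatinib",
    cell_line: str | None = None,
) -> pd.DataFrame:
    """Rank ECMs within one ligand and arm by their MEP median.

    Count and EdU-fraction axes are reported separately (long format), with
    each ECM's deviation from the ligand's across-ECM median. Ties are ranked
    in ECM label order.
    """
    sub = summary[(summary["ligand"] == ligand) & (summary["treatment"] == treatment)]
    if cell_line is not None:
        sub = sub[sub["cell_line"] == cell_line]
    if sub["ecm"].nunique() < 2:
        raise NumericalError(f"ligand {ligand!r} has fewer than 2 ECMs in arm {treatment!r}")
    frames = []
    for (cl,), arm in sub.groupby(["cell_line"], sort=True):
        for metric, (col, _) in METRIC_COLUMNS.items():
            d = arm[["ecm", col]].rename(columns={col: "value"}).copy()
            d = d.sort_values(["value", "ecm"], ascending=[False, True], ignore_index=True)
            d.insert(0, "cell_line", cl)
            d.insert(2, "metric", metric)
            d["deviation"] = d["value"] - d["value"].median()
            d["rank"] = np.arange(1, len(d) + 1)
            frames.append(d)
    return pd.concat(frames, ignore_index=True)


def two_sample_t(group_a, group_b) -> tuple[float, float]:
    """Unpaired, equal-variance (pooled) two-sample t-test, two-sided.

    Returns (t, p); zero pooled variance yields (NaN, NaN) with a warning.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups must be finite")
    pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
    if pooled == 0:
        warnings.warn("zero pooled variance; t statistic undefined", stacklevel=2)
        return np.nan, np.nan
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def exclude_conditions(
    summary: pd.DataFrame,
    exclusions: list[tuple[str, str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mask listed (condition label, metric) summary cells to NaN, with audit.

    Labels are matched against both the ECM and the ligand column (a label
    naming an ECM masks that ECM under every ligand, and vice versa); metrics
    are ``"cell_count"`` or ``"edu_fraction"``. Nothing is dropped: masked
    cells become NaN and every masked cell is listed in the audit table.
    Mirrors outlier-condition handling such as removing nidogen-spot counts.
    """
    out = summary.copy()
    audit_rows = []
    for label, metric in exclusions:
        if metric not in METRIC_COLUMNS:
            raise KeyError(f"unknown metric {metric!r}; expected one of {sorted(METRIC_COLUMNS)}")
        mask = (out["ecm"] == label) | (out["ligand"] == label)
        if not mask.any():
            raise KeyError(f"label {label!r} matches no ECM or ligand in the summary")
        for col in METRIC_COLUMNS[metric]:
            hit = mask & out[col].notna()
            for _, row in out.loc[hit, MEP_KEY].iterrows():
                audit_rows.append((*row, col, label, metric))
            out.loc[mask, col] = np.nan
    audit = pd.DataFrame(audit_rows, columns=MEP_KEY + ["column", "excluded_label", "metric"])
    return out, audit
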