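"""Randomized MEMA experimental designs.

A MEMA experiment prints extracellular-matrix (ECM) proteins as replicate
spots at random positions on the floor of each well of an 8-well plate.  One
soluble ligand is added per well, so a well ("array") realizes every
(ECM, ligand) combination present on its grid; the (ECM, ligand) pair is the
microenvironment perturbagen (MEP), the experimental unit of the screen.
Plates are replicated across cell lines and treatment arms (vehicle / drug).

The spot layout is randomized once per design and shared by every array, as a
single print run stamps the same physical pattern into each well.  This is
what lets downstream normalization arrange each signal as an arrays x spots
matrix with aligned columns.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import DesignError

#: Reserved labels: the control well contains no ligand (PBS), and every spot
#: is printed in a collagen-I carrier, so neither may name a panel member.
CONTROL_LIGAND = "PBS"
CARRIER_ECM = "COL1"

DEFAULT_CELL_LINES = ("AU565", "HCC1954")
DEFAULT_TREATMENTS = ("DMSO", "lapatinib")  # index 0 is the vehicle arm

MANIFEST_COLUMNS = [
    "cell_line", "treatment", "plate", "well", "array_id",
    "spot_row", "spot_col", "ecm", "ligand",
]


@dataclass
class ArrayDesign:
    """A full screen design.

    ``wells`` has one row per array (well) with its ligand and arm metadata;
    ``layout`` has one row per printed spot of the shared grid layout with
    0-based ``spot_row``/``spot_col`` coordinates and the ECM printed there.
    ``treatments[0]`` is the vehicle arm.
    """

    cell_lines: list[str]
    treatments: list[str]
    ecm_panel: list[str]
    ligand_panel: list[str]
    n_rows: int
    n_cols: int
    replicate_target: int
    wells_per_plate: int
    dropout_rate: float
    seed: int
    wells: pd.DataFrame = field(repr=False)
    layout: pd.DataFrame = field(repr=False)

    @property
    def vehicle_treatment(self) -> str:
        return self.treatments[0]

    @property
    def n_arrays(self) -> int:
        return len(self.wells)

    def to_manifest(self) -> pd.DataFrame:
        """One row per spot per array (0-based coordinates)."""
        return self.wells.merge(self.layout, how="cross")[MANIFEST_COLUMNS]

    def spot_keys(self) -> pd.DataFrame:
        """The (array_id, spot_row, spot_col) key set of the design."""
        return self.to_manifest()[["array_id", "spot_row", "spot_col"]]

    def validate(self) -> None:
        lay = self.layout
        if lay.duplicated(["spot_row", "spot_col"]).any():
            raise DesignError("duplicate spot coordinates in layout")
        if (lay["spot_row"] < 0).any() or (lay["spot_row"] >= self.n_rows).any() \
                or (lay["spot_col"] < 0).any() or (lay["spot_col"] >= self.n_cols).any():
            raise DesignError("spot coordinates outside the grid")
        counts = lay["ecm"].value_counts()
        lo, hi = max(1, self.replicate_target - 2), self.replicate_target
        if set(counts.index) != set(self.ecm_panel):
            raise DesignError("layout ECM set does not match the panel")
        if (counts < lo).any() or (counts > hi).any():
            raise DesignError(
                f"ECM replicate counts outside [{lo}, {hi}]: "
                f"{counts[(counts < lo) | (counts > hi)].to_dict()}")
        # one ligand per well; each ligand exactly once per arm; one control/plate
        for (cl, tr), arm in self.wells.groupby(["cell_line", "treatment"]):
            lig = arm.loc[arm["ligand"] != CONTROL_LIGAND, "ligand"]
            if sorted(lig) != sorted(self.ligand_panel):
                raise DesignError(f"arm ({cl}, {tr}) does not cover the ligand panel exactly once")
            per_plate = arm[arm["ligand"] == CONTROL_LIGAND].groupby("plate").size()
            if not (per_plate == 1).all() or len(per_plate) != arm["plate"].nunique():
                raise DesignError(f"arm ({cl}, {tr}) lacks exactly one control well per plate")


def build_design(
    n_ecm: int,
    n_ligand: int,
    replicate_target: int = 15,
    wells_per_plate: int = 8,
    seed: int = 0,
    *,
    n_rows: int = 20,
    n_cols: int = 35,
    cell_lines: tuple[str, ...] | list[str] = DEFAULT_CELL_LINES,
    treatments: tuple[str, ...] | list[str] = DEFAULT_TREATMENTS,
    ecm_names: list[str] | None = None,
    ligand_names: list[str] | None = None,
    dropout_rate: float = 0.0,
) -> ArrayDesign:
    """Construct a randomized design covering ``n_ecm`` ECMs x ``n_ligand`` ligands.

    Each plate holds ``wells_per_plate - 1`` ligand wells plus one PBS control
    well; enough plates are allocated per (cell line, treatment) arm to cover
    the ligand panel once.  Each ECM is printed ``replicate_target`` times at
    random grid positions; with ``dropout_rate > 0`` individual spots are
    removed at design time (at most 2 per ECM) to emulate the replicate-count
    jitter seen after printing QC.

    The same ``seed`` always yields the identical design.
    """
    if n_ecm < 1 or n_ligand < 1:
        raise DesignError("need at least one ECM and one ligand")
    if wells_per_plate < 2:
        raise DesignError("wells_per_plate must be >= 2 (one ligand well plus the control)")
    if replicate_target < 1:
        raise DesignError("replicate_target must be >= 1")
    capacity = n_rows * n_cols
    if capacity < n_ecm * replicate_target:
        raise DesignError(
            f"design infeasible: grid capacity {n_rows}x{n_cols}={capacity} cannot hold "
            f"{n_ecm} ECMs x {replicate_target} replicates = {n_ecm * replicate_target} spots")

    ecm_names = list(ecm_names) if ecm_names is not None else [f"ECM{i + 1:02d}" for i in range(n_ecm)]
    ligand_names = list(ligand_names) if ligand_names is not None else [f"LIG{i + 1:02d}" for i in range(n_ligand)]
    if len(ecm_names) != n_ecm or len(ligand_names) != n_ligand:
        raise DesignError("panel name lists must match the requested panel sizes")
    for reserved in (CONTROL_LIGAND, CARRIER_ECM):
        if reserved in ecm_names or reserved in ligand_names:
            raise DesignError(f"{reserved!r} is a reserved label and cannot name a panel member")
    if len(set(ecm_names)) != n_ecm or len(set(ligand_names)) != n_ligand:
        raise DesignError("panel names must be unique")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))

    # --- shared print layout -------------------------------------------------
    reps = np.full(n_ecm, replicate_target)
    if dropout_rate > 0:
        max_drop = min(2, replicate_target - 1)
        reps = replicate_target - np.minimum(
            rng.binomial(replicate_target, dropout_rate, size=n_ecm), max_drop)
    labels = np.repeat(ecm_names, reps)
    flat = rng.permutation(capacity)[: len(labels)]
    layout = pd.DataFrame({
        "spot_row": flat // n_cols,
        "spot_col": flat % n_cols,
        "ecm": labels,
    }).sort_values(["spot_row", "spot_col"], ignore_index=True)

    # --- ligand -> well assignment, identical across arms --------------------
    per_plate = wells_per_plate - 1
    order = [ligand_names[i] for i in rng.permutation(n_ligand)]
    plate_ligands = [order[i:i + per_plate] for i in range(0, n_ligand, per_plate)]
    rows = []
    for cl in cell_lines:
        for tr in treatments:
            for p, ligs in enumerate(plate_ligands, start=1):
                for w, lig in enumerate(ligs + [CONTROL_LIGAND], start=1):
                    rows.append((cl, tr, p, w, f"{cl}_{tr}_p{p:02d}_w{w:02d}", lig))
    wells = pd.DataFrame(rows, columns=["cell_line", "treatment", "plate", "well", "array_id", "ligand"])

    design = ArrayDesign(
        cell_lines=list(cell_lines), treatments=list(treatments),
        ecm_panel=ecm_names, ligand_panel=ligand_names,
        n_rows=n_rows, n_cols=n_cols, replicate_target=replicate_target,
        wells_per_plate=wells_per_plate, dropout_rate=float(dropout_rate),
        seed=int(seed), wells=wells, layout=layout,
    )
    design.validate()
    return design


def enumerate_meps(design: ArrayDesign, include_control: bool = False) -> int:
    """Number of distinct (ECM, ligand) pairs realized by the design.

    The PBS control wells are excluded unless ``include_control`` is set.
    """
    wells = design.wells
    if not include_control:
        wells = wells[wells["ligand"] != CONTROL_LIGAND]
    pairs = {
        (e, l)
        for l in wells["ligand"].unique()
        for e in design.layout["ecm"].unique()
    }
    return len(pairs)


def count_arrays(design: ArrayDesign) -> int:
    """Total number of arrays (= wells) across all cell lines, treatments and plates."""
    return int(len(design.wells))


# --- manifest / sidecar round-trip ------------------------------------------

def design_manifest_csv(design: ArrayDesign, version: str = "") -> str:
    """Render the per-spot manifest as CSV text with 1-based exported coordinates."""
    man = design.to_manifest().copy()
    man["spot_row"] += 1
    man["spot_col"] += 1
    buf = io.StringIO()
    buf.write("# memascreen design manifest")
    buf.write(f" v{version}\n" if version else "\n")
    buf.write("# spot_row and spot_col are 1-based in this file (0-based in memory)\n")
    man.to_csv(buf, index=False)
    return buf.getvalue()


def write_design(design: ArrayDesign, out_dir) -> None:
    """Write ``design.csv`` (per-spot manifest) plus ``design.yaml`` sidecar."""
    from pathlib import Path
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "design.csv").write_text(design_manifest_csv(design, __version__))
    sidecar = {
        "cell_lines": design.cell_lines,
        "treatments": design.treatments,
        "ecm_panel": design.ecm_panel,
        "ligand_panel": design.ligand_panel,
        "n_rows": design.n_rows,
        "n_cols": design.n_cols,
        "replicate_target": design.replicate_target,
        "wells_per_plate": design.wells_per_plate,
        "dropout_rate": design.dropout_rate,
        "seed": design.seed,
    }
    (out / "design.yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))


def read_design(in_dir) -> ArrayDesign:
    """Read a design written by :func:`write_design`; inverse on every field."""
    from pathlib import Path

    inp = Path(in_dir)
    meta = yaml.safe_load((inp / "design.yaml").read_text())
    man = pd.read_csv(inp / "design.csv", comment="#")
    man["spot_row"] -= 1
    man["spot_col"] -= 1
    wells = (man[["cell_line", "treatment", "plate", "well", "array_id", "ligand"]]
             .drop_duplicates(ignore_index=True))
    first_array = man["array_id"].iloc[0]
    layout = (man.loc[man["array_id"] == first_array, ["spot_row", "spot_col", "ecm"]]
              .reset_index(drop=True))
    design = ArrayDesign(wells=wells, layout=layout, **meta)
    design.validate()
    return design
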