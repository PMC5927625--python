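"""Typed CSV round-tripping and pipeline configuration.

Every file written by the package starts with ``#`` comment lines recording
the tool version and the resolved parameters of the producing stage; readers
skip them. Schemas are column -> dtype maps; reading validates the header
exactly and reports the delta on mismatch.
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError, SchemaError

CELL_SCHEMA = {
    "array_id": str, "spot_row": int, "spot_col": int, "cell_id": int,
    "dapi_total_intensity": float, "edu_mean_intensity": float,
    "krt14_intensity": float, "krt19_intensity": float, "nuclear_area": float,
}
#: ground truth exists only in simulated tables; gate label only after gating
CELL_OPTIONAL = {"edu_true_label": bool, "apoptotic_true_label": bool, "edu_pos": bool}

SPOT_SCHEMA = {
    "array_id": str, "spot_row": int, "spot_col": int, "ecm": str, "ligand": str,
    "treatment": str, "cell_line": str, "cell_count": float, "edu_fraction": float,
    "krt14_median": float, "krt19_median": float, "nuclear_area_median": float,
    "n_excluded": int,
}

MEP_SCHEMA = {
    "cell_line": str, "treatment": str, "ecm": str, "ligand": str,
    "median_cell_count": float, "median_edu_fraction": float,
    "sem_cell_count": float, "sem_edu_fraction": float, "n_replicates": int,
}


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a CSV with a version/parameter comment header."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    buf.write(f"# memascreen v{__version__}\n")
    for k, v in (meta or {}).items():
        buf.write(f"# {k}={v}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def read_table(path, schema: dict | None = None,
               optional: dict | None = None) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, validating against ``schema``."""
    df = pd.read_csv(path, comment="#")
    if schema is not None:
        optional = optional or {}
        have, want = set(df.columns), set(schema)
        missing = sorted(want - have)
        extra = sorted(have - want - set(optional))
        if missing or extra:
            raise SchemaError(
                f"{path}: schema mismatch; missing columns {missing}, unexpected columns {extra}")
        for col, typ in {**schema, **optional}.items():
            if col in df.columns:
                df[col] = df[col].astype(typ)
    return df


@dataclass
class PipelineConfig:
    """Resolved configuration of one full pipeline run; unknown keys rejected."""

    out_dir: str = "mema_out"
    seed: int = 0
    # design / simulation (used when no cells table is supplied)
    design_dir: str | None = None
    cells_path: str | None = None
    simulate: bool = True
    n_ecm: int = 6
    n_ligand: int = 8
    replicate_target: int = 15
    wells_per_plate: int = 5
    n_rows: int = 10
    n_cols: int = 10
    dropout_rate: float = 0.05
    cell_lines: list[str] = field(default_factory=lambda: ["AU565", "HCC1954"])
    treatments: list[str] = field(default_factory=lambda: ["DMSO", "lapatinib"])
    # summarization
    gate_scope: str = "array_id"
    min_area: float | None = None
    max_area: float | None = None
    # normalization
    k_unwanted: int = 3
    loess_span: float = 0.5
    loess_degree: int = 2
    signals: list[str] | None = None
    # scoring
    reference_ligand: str = "PBS"
    drug_treatment: str | None = None  # default: treatments[1]
    exclusions: list = field(default_factory=list)
    verbosity: int = 1

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {unknown}")
        try:
            return cls(**data)
        except TypeError as e:
            raise ConfigError(str(e)) from e

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: configuration must be a mapping")
        return cls.from_dict(data)

    def snapshot(self, path) -> None:
        """Write the fully resolved configuration next to the outputs."""
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
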