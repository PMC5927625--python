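"""Synthetic per-cell tables with the structure the analysis assumes.

The generator emulates what a segmentation pipeline emits for a MEMA screen:
one row per nucleus with its spot assignment, DAPI total intensity, EdU mean
intensity, keratin stain intensities and nuclear area.  The generative model
plants exactly the effects the downstream stages are meant to recover or
remove:

* per-spot expected cell count
  ``lambda = baseline * ecm_effect * ligand_effect * drug_term
  * exp(spatial(row, col) + batch(array))`` with Poisson (optionally
  negative-binomial) counts;
* ``drug_term = 1`` under vehicle and
  ``drug_effect + rho * (1 - drug_effect)`` under drug, where ``rho`` is the
  ligand's rescue strength (``rho = 1`` fully cancels the drug effect,
  ``rho > 1`` over-stimulates past the vehicle level);
* EdU positivity per cell is Bernoulli with the spot's base S-phase fraction
  scaled by the same drug/rescue term, and EdU intensity is a two-component
  log-normal mixture so auto-gating is well posed;
* a smooth, zero-mean spatial surface per array (the artifact bivariate LOESS
  removes) and a per-array log-scale batch offset (the variation RUV and
  replicate summarization must tolerate);
* a fraction of apoptotic cells with shrunken nuclei, giving the size gate
  something to exclude.

Ground-truth columns (``edu_true_label``, ``apoptotic_true_label``) are kept
so gating and filtering can be scored exactly; they exist only in simulated
tables.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .design import ArrayDesign, build_design
from .errors import ParameterError

CELL_COLUMNS = [
    "array_id", "spot_row", "spot_col", "cell_id",
    "dapi_total_intensity", "edu_mean_intensity",
    "krt14_intensity", "krt19_intensity", "nuclear_area",
    "edu_true_label", "apoptotic_true_label",
]

# sub-stream tags for per-array seed derivation (counter scheme)
_STREAM_CELLS, _STREAM_SPATIAL, _STREAM_BATCH = 7000, 7001, 7002


def _array_key(array_id: str) -> int:
    """Stable 32-bit key for an array id, independent of Python hashing."""
    return zlib.crc32(array_id.encode())


@dataclass
class SimulationParams:
    """Generative parameters; defaults are the reference screen conditions.

    Intensities are in arbitrary fluorescence units; their ``*_mean``/``*_sd``
    parameters are natural-log-scale log-normal parameters.  Areas are in
    pixel^2 (log-scale parameters likewise).
    """

    baseline_cells_per_spot: float = 100.0
    ecm_effects: dict[str, float] = field(default_factory=dict)
    ligand_effects: dict[str, float] = field(default_factory=dict)
    drug_effect: float = 0.3
    rescue: dict[str, float] = field(default_factory=dict)
    spatial_amplitude: float = 1.0
    batch_sd: float = 0.03
    edu_base_fraction: float = 0.35
    edu_neg_mean: float = 2.0
    edu_pos_mean: float = 4.0
    edu_sd: float = 0.4
    dapi_mean: float = 6.0
    dapi_sd: float = 0.3
    krt14_mean: float = 4.0
    krt19_mean: float = 5.0
    stain_sd: float = 0.5
    nuclear_area_mean: float = 5.5
    nuclear_area_sd: float = 0.25
    apoptotic_fraction: float = 0.05
    apoptotic_area_scale: float = 0.2
    nb_dispersion: float | None = None  # Gamma-Poisson overdispersion when set
    nuisance_mode: str = "log_additive"  # or "raw_multiplicative"
    seed: int = 0

    def validate(self) -> None:
        scalars = {k: v for k, v in asdict(self).items()
                   if isinstance(v, (int, float)) and v is not None}
        for k, v in scalars.items():
            if not np.isfinite(v):
                raise ParameterError(f"parameter {k} is not finite: {v}")
        if self.edu_pos_mean <= self.edu_neg_mean:
            raise ParameterError("edu_pos_mean must exceed edu_neg_mean")
        for k in ("edu_base_fraction", "apoptotic_fraction"):
            if not 0 <= getattr(self, k) <= 1:
                raise ParameterError(f"{k} must be a probability in [0, 1]")
        for k in ("edu_sd", "dapi_sd", "stain_sd", "nuclear_area_sd", "batch_sd"):
            if getattr(self, k) < 0:
                raise ParameterError(f"{k} must be >= 0")
        if self.baseline_cells_per_spot <= 0:
            raise ParameterError("baseline_cells_per_spot must be positive")
        for name, eff in (("ecm_effects", self.ecm_effects),
                          ("ligand_effects", self.ligand_effects),
                          ("rescue", self.rescue)):
            for lab, v in eff.items():
                if not np.isfinite(v) or v < 0:
                    raise ParameterError(f"{name}[{lab!r}] must be finite and >= 0, got {v}")
        if self.nuisance_mode not in ("log_additive", "raw_multiplicative"):
            raise ParameterError(f"unknown nuisance_mode {self.nuisance_mode!r}")


def spatial_field(array_id: str, n_rows: int, n_cols: int,
                  params: SimulationParams) -> np.ndarray:
    """Deterministic smooth surface over the whole grid of one array.

    A low-order polynomial plus one low-frequency sinusoid with array-specific
    coefficients, centered to mean zero over the grid and scaled so
    ``max |surface| == spatial_amplitude`` (exactly zero at amplitude 0).
    """
    if params.spatial_amplitude == 0:
        return np.zeros((n_rows, n_cols))
    rng = np.random.default_rng(
        np.random.SeedSequence([int(params.seed), _STREAM_SPATIAL, _array_key(array_id)]))
    # grid coordinates on [-1, 1] in each dimension (constant when size 1)
    r = np.linspace(-1.0, 1.0, n_rows) if n_rows > 1 else np.zeros(1)
    c = np.linspace(-1.0, 1.0, n_cols) if n_cols > 1 else np.zeros(1)
    x, y = np.meshgrid(c, r)
    a = rng.normal(size=3)
    theta, phase = rng.uniform(0, 2 * np.pi, size=2)
    freq = rng.uniform(0.3, 0.8)
    raw = (a[0] * x + a[1] * y + a[2] * x * y
           + np.sin(np.pi * freq * (x * np.cos(theta) + y * np.sin(theta)) + phase))
    raw = raw - raw.mean()
    peak = np.abs(raw).max()
    if peak > 0:
        raw *= params.spatial_amplitude / peak
    return raw


def spatial_surface(array_id: str, spot_row: int, spot_col: int,
                    params: SimulationParams, n_rows: int = 20, n_cols: int = 35) -> float:
    """Surface value at one grid coordinate (see :func:`spatial_field`)."""
    if not (0 <= spot_row < n_rows and 0 <= spot_col < n_cols):
        raise ParameterError(f"coordinate ({spot_row}, {spot_col}) outside {n_rows}x{n_cols} grid")
    return float(spatial_field(array_id, n_rows, n_cols, params)[spot_row, spot_col])


def batch_offset(array_id: str, params: SimulationParams) -> float:
    """Per-array log-scale batch offset, N(0, batch_sd), reproducible per array."""
    if params.batch_sd == 0:
        return 0.0
    rng = np.random.default_rng(
        np.random.SeedSequence([int(params.seed), _STREAM_BATCH, _array_key(array_id)]))
    return float(rng.normal(0.0, params.batch_sd))


def drug_term(ligand: str, params: SimulationParams) -> float:
    """Drug-arm multiplier: drug_effect + rho * (1 - drug_effect)."""
    rho = params.rescue.get(ligand, 0.0)
    return params.drug_effect + rho * (1.0 - params.drug_effect)


def expected_spot_rate(ecm: str, ligand: str, treatment_is_vehicle: bool,
                       params: SimulationParams) -> float:
    """Expected cell count of a spot before spatial/batch nuisances."""
    term = 1.0 if treatment_is_vehicle else drug_term(ligand, params)
    return (params.baseline_cells_per_spot
            * params.ecm_effects.get(ecm, 1.0)
            * params.ligand_effects.get(ligand, 1.0)
            * term)


def expected_log_levels(design: ArrayDesign, params: SimulationParams,
                        treatment: str) -> pd.DataFrame:
    """Ground-truth expected log cell count per (ecm, ligand) for one arm.

    Used to score how well the estimated MEP medians recover the planted
    effects; nuisances are excluded by construction (they are noise).
    """
    is_vehicle = treatment == design.vehicle_treatment
    rows = [
        (e, l, np.log(expected_spot_rate(e, l, is_vehicle, params)))
        for e in design.ecm_panel
        for l in design.ligand_panel
    ]
    return pd.DataFrame(rows, columns=["ecm", "ligand", "true_log_level"])


def simulate_experiment(design: ArrayDesign, params: SimulationParams) -> pd.DataFrame:
    """Draw a per-cell table for the whole design. Same seed, same table."""
    params.validate()
    frames = []
    layout = design.layout
    ecm_mult = layout["ecm"].map(lambda e: params.ecm_effects.get(e, 1.0)).to_numpy()
    n_spots = len(layout)

    for well in design.wells.itertuples(index=False):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(params.seed), _STREAM_CELLS, _array_key(well.array_id)]))
        surf = spatial_field(well.array_id, design.n_rows, design.n_cols, params)
        spot_spatial = surf[layout["spot_row"].to_numpy(), layout["spot_col"].to_numpy()]
        batch = batch_offset(well.array_id, params)
        is_vehicle = well.treatment == design.vehicle_treatment
        term = 1.0 if is_vehicle else drug_term(well.ligand, params)
        base = (params.baseline_cells_per_spot * ecm_mult
                * params.ligand_effects.get(well.ligand, 1.0) * term)
        if params.nuisance_mode == "log_additive":
            lam = base * np.exp(spot_spatial + batch)
        else:
            lam = base * np.clip(1.0 + spot_spatial, 0.05, None) * np.clip(1.0 + batch, 0.05, None)
        if not np.all(np.isfinite(lam)) or lam.max() > 1e7:
            raise ParameterError(
                f"expected count overflow on array {well.array_id} (max lambda {lam.max():.3g})")
        if params.nb_dispersion is None:
            counts = rng.poisson(lam)
        else:
            # Gamma-Poisson: var = lam + lam^2 / dispersion
            counts = rng.poisson(rng.gamma(params.nb_dispersion, lam / params.nb_dispersion))

        n_cells = int(counts.sum())
        if n_cells == 0:
            continue
        spot_idx = np.repeat(np.arange(n_spots), counts)
        p_edu = np.clip(params.edu_base_fraction * term, 1e-4, 1 - 1e-4)
        edu_pos = rng.random(n_cells) < p_edu
        log_mu = np.where(edu_pos, params.edu_pos_mean, params.edu_neg_mean)
        apoptotic = rng.random(n_cells) < params.apoptotic_fraction
        area = np.exp(rng.normal(params.nuclear_area_mean, params.nuclear_area_sd, n_cells))
        area = np.where(apoptotic, area * params.apoptotic_area_scale, area)
        frames.append(pd.DataFrame({
            "array_id": well.array_id,
            "spot_row": layout["spot_row"].to_numpy()[spot_idx],
            "spot_col": layout["spot_col"].to_numpy()[spot_idx],
            "cell_id": np.arange(n_cells),
            "dapi_total_intensity": np.exp(rng.normal(params.dapi_mean, params.dapi_sd, n_cells)),
            "edu_mean_intensity": np.exp(rng.normal(log_mu, params.edu_sd)),
            "krt14_intensity": np.exp(rng.normal(params.krt14_mean, params.stain_sd, n_cells)),
            "krt19_intensity": np.exp(rng.normal(params.krt19_mean, params.stain_sd, n_cells)),
            "nuclear_area": area,
            "edu_true_label": edu_pos,
            "apoptotic_true_label": apoptotic,
        }))
    if not frames:
        return pd.DataFrame(columns=CELL_COLUMNS)
    return pd.concat(frames, ignore_index=True)[CELL_COLUMNS]


# --- canned fixture experiment ----------------------------------------------

FIXTURE_ECM = ["COL4", "FN1", "LAMB1", "NID1", "TNC", "THBS1"]
FIXTURE_LIGANDS = ["NRG1B", "EGF", "HGF", "FGF2", "IGF1", "TGFB1", "CXCL12", "BMP2"]


def fixture_design(seed: int = 0, *, cell_lines: tuple[str, ...] = ("AU565", "HCC1954"),
                   replicate_target: int = 15) -> ArrayDesign:
    """Small canned design: 6 ECM x 8 ligands, 2 plates of 4 ligands + control per arm."""
    return build_design(
        len(FIXTURE_ECM), len(FIXTURE_LIGANDS),
        replicate_target=replicate_target, wells_per_plate=5, seed=seed,
        n_rows=10, n_cols=10, cell_lines=cell_lines,
        ecm_names=FIXTURE_ECM, ligand_names=FIXTURE_LIGANDS, dropout_rate=0.05)


def fixture_params(seed: int = 0, *, planted_ligand: str = "NRG1B",
                   rho: float = 1.2, effect_sd: float = 0.2) -> SimulationParams:
    """Reference-condition parameters with one planted rescue ligand.

    ECM and (non-planted) ligand baseline effects are drawn log-normally with
    ``effect_sd`` spread; the planted ligand's baseline effect is held at 1 so
    its rescue score is governed by ``rho`` alone.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 9000]))
    ecm_effects = {e: float(np.exp(rng.normal(0, effect_sd))) for e in FIXTURE_ECM}
    ligand_effects = {l: float(np.exp(rng.normal(0, effect_sd))) for l in FIXTURE_LIGANDS}
    ligand_effects[planted_ligand] = 1.0
    return SimulationParams(
        ecm_effects=ecm_effects, ligand_effects=ligand_effects,
        rescue={planted_ligand: rho}, seed=seed)
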