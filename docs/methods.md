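# Methods

## Design model

A design is the cross of cell lines × treatment arms × plates × wells, where
each well is one **array** carrying the shared printed spot grid.  Plates
hold `wells_per_plate − 1` ligand wells plus one PBS control well; enough
plates are allocated per arm to cover the ligand panel exactly once.  With
the reference values (46 ECM, 56 ligands, 8-well plates, 2 cell lines ×
2 arms) this yields 8 plates per arm and 256 arrays, realizing 2,576
ECM × ligand combinations.

The spot layout is randomized **once per design** and shared by every array:
a single print run stamps the same physical pattern into each well.  This is
also what makes the arrays × spots signal matrices column-aligned, which the
normalizer requires.  Each ECM receives `replicate_target` spots (default
15) at uniformly random grid positions; an optional design-time dropout
(0.05/spot in the canned fixture, at most 2 spots per ECM) reproduces the
13–15 replicate jitter of post-printing QC.  The grid defaults to 20 × 35
(700 positions ≥ 46 × 15 = 690 printed spots): the smallest near-square grid
holding the replicate load; it is configurable.  Coordinates are 0-based
row-major in memory and 1-based in exported manifests (microscopy
convention, stated in the file header).  `PBS` (control well) and `COL1`
(the collagen-I printing carrier present in every spot) are reserved labels.

Randomness: one master seed; per-array sub-streams are derived as
`SeedSequence([seed, stream_tag, crc32(array_id)])`, so any array is
independently reproducible and the whole design/simulation is byte-stable
under a fixed seed.

## Generative model (synthetic data)

Per spot, the expected cell count is

    lambda = baseline * ecm_effect * ligand_effect * drug_term
             * exp(spatial(row, col) + batch(array))

with `drug_term = 1` under vehicle and `drug_effect + rho*(1 − drug_effect)`
under drug (`rho` = the ligand's rescue strength; `rho = 1` cancels the drug
effect, `rho > 1` over-stimulates).  Counts are Poisson (optional
Gamma–Poisson overdispersion via `nb_dispersion`).  Per cell, EdU positivity
is Bernoulli with the base S-phase fraction scaled by the same drug/rescue
term; EdU intensity is a two-component log-normal mixture (the minimal
structure under which auto-gating is well posed); DAPI, keratin stains and
nuclear area are log-normal; an `apoptotic_fraction` of cells has its
nucleus shrunk by `apoptotic_area_scale`, giving the size gate true
positives to remove.  Ground-truth labels (`edu_true_label`,
`apoptotic_true_label`) are emitted only by the simulator.

Nuisances act additively on the log scale by default, matching the
additive-on-transformed-scale model the normalizer assumes; a
`raw_multiplicative` switch exists for mis-specification robustness checks.
The spatial surface is a centered low-order polynomial plus one
low-frequency sinusoid (≤ ~1 period across the array) with array-specific
coefficients, scaled so `max |surface| = spatial_amplitude` and exactly zero
mean over the grid.

### Reference conditions and why

| parameter | default | rationale |
| --- | --- | --- |
| `baseline_cells_per_spot` | 100 | ~2.5×10⁵ cells seeded per well over ~700 spots with partial attachment |
| `drug_effect` | 0.3 | a strong growth-arresting dose (70% count reduction) |
| planted `rho` | 1.2 (fixture) | a rescue that over-stimulates slightly past vehicle control |
| ECM/ligand effect spread | 0.2 log-e (fixture) | ±20% typical microenvironment modulation |
| `spatial_amplitude` | 1.0 | strong edge/printing gradients, up to ~2.7× across an array |
| `batch_sd` | 0.03 | array-level technical CV within one print/stain/image batch |
| EdU mixture | log-means 2.0/4.0, SD 0.4, base fraction 0.35 | well-separated but overlapping S-phase signal |

`batch_sd` deserves a note.  The screen design assigns each ligand one well
per arm, so array-level variation is structurally confounded with the ligand
effect, and the normalization deliberately preserves array level (replicate
residual controls contain no array-constant component, and LOESS restores
each array's median).  The screen is therefore only informative when
array-level technical variation is small relative to the effects of
interest; a power analysis at the fixture scale showed planted-rescue
recovery degrades once `batch_sd` approaches the rescue margin
(log 1.14 ≈ 0.13), and 0.03 (3% CV) represents the tightly controlled
single-batch regime the assay presupposes.  Under these conditions the
planted ligand is recovered at rank 1 with S > 1 in ~9 of 10 simulated
screens (19–20 of the 20 fixed seeds used by the test suite).

## Spot summarization

* **Size gate**: nuclei outside `[min_area, max_area]` are excluded; by
  default the gate is relative — [0.3, 3.0] × the per-array median area —
  which is scale-free and needs no pixel calibration.  Excluded counts are
  kept per spot (`n_excluded`) so cells are conserved.
* **EdU auto-gate**: per group (default per array, since staining drifts
  between arrays) a 2-component Gaussian mixture is fitted to log intensity
  and cut at the equal-posterior point (the quantile-initialized fit and the
  fixed SVD/optimizer seeds make it deterministic).  Degenerate fits
  (component weight < 0.01, means closer than 0.5 SD, or no posterior
  crossing) fall back to Otsu's threshold and are flagged; groups under 50
  cells borrow the global threshold.  Thresholds, methods and flags are
  reported per group.
* **Summaries**: per printed spot — nuclei count, EdU⁺ fraction (NaN when
  empty), stain and morphology medians.  Spots with zero surviving cells are
  emitted with count 0 so replicate bookkeeping stays aligned with the
  design; they are excluded from medians downstream.

## Normalization

Signals are transformed before fitting and back-transformed after:
`log2(x+1)` for counts, logit with ε = 1/(2·max count) clamping for
fractions, `log2` for intensities and areas.  The transform and ε are
recorded in the matrix and inverted exactly on write-out; NaNs are excluded
from medians and fits and pass through unchanged.

**RUV.** Controls are replicate-median residuals: per array, each spot minus
the median of that array's spots sharing its ECM (a single-replicate ECM has
residual 0, counted and warned).  The rank-k truncated SVD of the residual
matrix (k = 3 by default; a scree of singular values is always emitted so
users can pick k) is subtracted from the data.  Sign convention: the
largest-magnitude spot loading of each component is positive, making the
decomposition deterministic.  `k = 0` is the exact identity; k above the
residual matrix's numerical rank raises an error naming the achievable rank.
This construction removes exactly the technical variation visible to
replicate controls — by design it cannot (and should not) remove
array-constant shifts.

**Bivariate LOESS.** Per array, a local-polynomial surface over (spot_row,
spot_col) with tricube weights over the nearest `ceil(span · n)` spots is
fitted and subtracted, and the array's pre-fit median restored.  Defaults:
span 0.5, degree 2.  Degree 2 (local-quadratic) is the default because the
generator's smooth surfaces — and plausible real artifacts — carry
curvature that a local-linear fit demonstrably leaves behind as a
surface-correlated residual; degree is configurable in {1, 2}.  A span
leaving fewer than 6 points per local fit raises an error stating the
minimal feasible span.  The correction is invariant (to 1e-9) to adding a
constant to an array, by construction.

Order is fixed as RUV → LOESS.  Stage parameters, singular values and
fitted surfaces are retained in `NormalizationModel` objects; re-applying a
stored surface reproduces the correction exactly.

## Scoring

MEP summaries are medians/SEM/n over replicate spots per (cell line,
treatment, ECM, ligand); SEM = sample SD/√n over the contributing
(non-empty) spots.  `response_ratio` divides treated by control summaries
per MEP (zero control → NaN with warning, never ±∞).  `rescue_score`
implements S(ℓ) = (T_ℓ − T_ref)/(C_ref − T_ref); given a spot table it pools
the medians over all ECM spots of the ligand (the preferred, lower-variance
estimator), given a MEP summary it uses the median of ECM-level medians.  It
refuses to score when the reference shows no drug effect (C_ref ≤ T_ref).
S is invariant to common affine rescaling of all medians.  Count-based and
EdU-based scores are computed separately and never averaged.
`ecm_modifier_rank` ranks ECMs within a ligand and arm by MEP median (ties
in label order) with deviations from the across-ECM median.
`two_sample_t` is the classical pooled-variance unpaired two-sided t-test
(zero pooled variance → NaN with a diagnostic), and `exclude_conditions`
masks named (condition, metric) cells to NaN with a full audit trail — the
mechanism for outlier conditions such as dropping nidogen-spot counts —
rather than silently deleting rows.  Benjamini–Hochberg adjustment is left
to the caller's multiple-testing needs; reported p-values are raw.

## What the simulator does and does not emulate

It reproduces the statistical structure the pipeline assumes: replicate
spots at random positions, per-well ligands, multiplicative condition
effects, log-additive smooth spatial artifacts and array offsets, Poisson
counting noise, a bimodal EdU intensity, and apoptotic outliers.  It does
not model segmentation errors, cell–cell contact effects, spot-to-spot
carryover, focus artifacts, non-smooth (e.g. scratch or bubble) defects, or
any real ECM/ligand biology — effect magnitudes are illustrative, not
calibrated to any dataset.  Passing tests therefore demonstrate correctness
of the computations and recoverability under the stated noise model, not
biological validity on real screens.

## Problem sizes and numerics

The test suite and the acceptance script run the canned fixture (6 ECM × 8
ligands, 10×10 grid, one or two cell lines, ~100 cells/spot, ~10⁵ cells per
simulated screen) and a one-arm 46-ECM design (8 arrays × 690 spots) for the
spatial checks; the full 256-array geometry is exercised for design
enumeration, and all algorithms scale to it directly (a full-geometry
normalization of one signal is a 256×690 SVD plus 256 LOESS fits).
Equality assertions use 1e-8 absolute tolerance unless a contract states
exactness; byte-identical rerun checks compare written CSV files directly.

## Known limitations

* Array-level (well-level) technical variation cannot be separated from
  ligand effects by this design; it is preserved, not corrected.
* The RUV variant is the residual-SVD construction described above; it is
  not a general RUV-2/RUV-III estimator with arbitrary control sets.
* LOESS is fitted per array independently; no information is shared across
  arrays beyond the RUV stage.
* The EdU gate uses intensity only; DAPI total intensity is carried through
  for inspection but does not enter the threshold.
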