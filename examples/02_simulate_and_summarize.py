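"""Simulate a small screen and reduce per-cell data to per-spot features.

The canned experiment plants a rescue ligand (NRG1B at rho = 1.2 under a
drug_effect of 0.3), a smooth spatial artifact per array, and a small
array-level batch offset.  Cells are size-gated (apoptotic nuclei removed),
EdU intensity is auto-gated per array by a two-component mixture fit, and
spots are median-summarized.
"""

import memascreen as ms

design = ms.fixture_design(seed=0)          # 6 ECM x 8 ligands, 2 cell lines
params = ms.fixture_params(seed=0)          # plants NRG1B rescue at rho = 1.2
cells = ms.simulate_experiment(design, params)
print(f"simulated {len(cells):,} cells on {design.n_arrays} arrays")

kept, excluded = ms.filter_nuclei(cells)    # relative size gate [0.3, 3] x median
print(f"size gate excluded {len(excluded):,} nuclei "
      f"({excluded.apoptotic_true_label.mean():.0%} of them truly apoptotic)")

gated, report = ms.gate_edu(kept)           # per-array mixture threshold
print(f"EdU auto-gate: {report.method.value_counts().to_dict()}, "
      f"mean threshold {report.threshold.mean():.2f} (log intensity)")

spots = ms.summarize_spots(gated, design, excluded)
print(f"spot table: {len(spots):,} rows (one per printed spot)")
print(spots[["ecm", "ligand", "treatment", "cell_count", "edu_fraction"]].head())
# cell_count is the DAPI-based nuclei count per spot; edu_fraction the
# proportion of EdU+ (S-phase) nuclei — the proliferation readout.
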