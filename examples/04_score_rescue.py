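"""End-to-end rescue scoring: which ligand lets cells ignore the drug?

The rescue score S(l) = (T_l - T_ref) / (C_ref - T_ref) compares each
ligand's drug-arm median cell count (T_l) with the control ligand under drug
(T_ref) and under vehicle (C_ref): S = 0 means no rescue, S = 1 full
restoration to vehicle-control growth, S > 1 stimulation beyond it.
"""

import memascreen as ms

design = ms.fixture_design(seed=0, cell_lines=("AU565",))
params = ms.fixture_params(seed=0)          # plants NRG1B at rho = 1.2
cells = ms.simulate_experiment(design, params)

res = ms.analyze_experiment(cells, design, signals=["cell_count", "edu_fraction"])
hits = res["hits"]
print(hits[["ligand", "rescue_score", "treated_median", "control_median", "rank"]]
      .to_string(index=False))

top = hits.iloc[0]
print(f"\ntop hit: {top.ligand} with S = {top.rescue_score:.2f} "
      f"(planted rescue strength was 1.2)")

# Which matrix proteins modulate the top ligand's effect?
ecm = ms.ecm_modifier_rank(res["mep"], top.ligand)
print("\nECM modifiers of the top ligand (cell-count axis):")
print(ecm[ecm.metric == "cell_count"][["ecm", "value", "deviation", "rank"]]
      .to_string(index=False))
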