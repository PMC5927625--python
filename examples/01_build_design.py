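"""Build the reference MEMA design and count what it realizes.

A MEMA screen prints 46 ECM proteins as ~15 replicate spots at random
positions in each well of 8-well plates; one of 56 soluble ligands (or the
PBS control) is added per well.  Two cell lines x two treatment arms of
8 plates each give 256 arrays.
"""

import memascreen as ms

design = ms.build_design(46, 56, replicate_target=15, wells_per_plate=8, seed=1)

print(f"arrays (wells) in the screen : {ms.count_arrays(design)}")
print(f"distinct MEPs (ECM x ligand) : {ms.enumerate_meps(design)}")
print(f"... including the PBS control: {ms.enumerate_meps(design, include_control=True)}")
print(f"printed spots per array      : {len(design.layout)} "
      f"on a {design.n_rows}x{design.n_cols} grid")

# The manifest is one row per spot per array; write it with its YAML sidecar.
ms.write_design(design, "scratch/design")
print("design manifest written to scratch/design/design.csv")
# Arrays: each well is imaged as one unit; the MEP count is what the screen
# assays; re-running with the same seed reproduces the file byte for byte.
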