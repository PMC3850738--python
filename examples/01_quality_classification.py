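"""Classify docked poses against their native complex.

Builds a small synthetic docking case (two helices plus rigid-body
perturbed decoys), computes fnat / IRMSD / LRMSD for every decoy and
prints the four-class quality table.
"""

from dockscore import SyntheticCaseSpec, default_schedule, make_case

spec = SyntheticCaseSpec(case_id="demo", n_decoys=20,
                         schedule=default_schedule(20), seed=7)
decoy_set, quality = make_case(spec)

print(quality[["fnat", "irmsd", "lrmsd", "quality"]].round(3).to_string())
print()
print("Class counts:", quality["quality"].value_counts().to_dict())
# fnat is the fraction of native residue contacts a decoy retains; LRMSD
# the ligand backbone RMSD after receptor superposition; IRMSD the
# backbone RMSD over native-interface residues.  Together they assign
# each pose one of incorrect / acceptable / medium / high.
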