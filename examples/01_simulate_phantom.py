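"""Simulate a small SUVR phantom cohort and inspect the class patterns.

Builds the 20-region toy atlas, simulates a few subjects per phenotype and
prints the mean SUVR in three diagnostically relevant regions. Expect the
putamen depressed in MSA, the caudate in PSP, and cortex mildly depressed
in IPD, relative to healthy controls (HC).
"""

import numpy as np

from radguide.phantom import PhantomDesign, make_toy_atlas, simulate_subject

design = PhantomDesign(seed=0)
atlas = make_toy_atlas(design)
labels = {name: lab for lab, name in atlas.region_table}

regions = ("putamen", "caudate", "frontal_cortex")
print(f"{'class':<6}" + "".join(f"{r:>16}" for r in regions))
for cls in ("HC", "IPD", "MSA", "PSP"):
    means = {r: [] for r in regions}
    for i in range(8):
        vol = simulate_subject(atlas, cls, design,
                               np.random.default_rng([cls == "HC", i, ord(cls[0])]))
        for r in regions:
            means[r].append(vol.data[atlas.labels == labels[r]].mean())
    print(f"{cls:<6}" + "".join(f"{np.mean(means[r]):>16.3f}" for r in regions))

print("\nValues are SUVR (brain-mask mean = 1); lower means = hypometabolism.")
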