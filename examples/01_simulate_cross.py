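"""Simulate the F2 mapping study and look at its segregation structure.

Builds the default tomato-like genome, simulates 129 F2 plants of the
highly-branched x single-branch cross, assigns two-locus branch-number
phenotypes, selects the 60-plant single-branch and 11-plant highly-branched
bulks, and prints the genotype-class table.
"""

import numpy as np

import bulkseg as bs

study = bs.simulate_study(n=129, n_sb=60, n_hb=11, seed=1)
pop = study.population

print(f"plants: {len(pop)}, markers: {study.genome.n_snps}")
print(f"population draws until both bulks were feasible: {study.n_population_draws}")
print(f"bulk sizes: SB={len(study.sb_ids)}, HB={len(study.hb_ids)}")

classes = pop.genotype_classes()
print("\ngenotype classes (9:3:3:1 expected over F_S_/F_ss/ffS_/ffss):")
for cls in ("F_S_", "F_ss", "ffS_", "ffss"):
    n = int((classes == cls).sum())
    med = np.median(pop.bn_median[classes == cls])
    print(f"  {cls}: n={n:3d}  median plant BN={med:g}")

n_hb = int((pop.bn_median > 16).sum())
res = bs.chi_square_gof([len(pop) - n_hb, n_hb], "15:1")
print(
    f"\nhighly-branched plants (median BN > 16): {n_hb} of {len(pop)}; "
    f"15:1 chi-square = {res.statistic:.2f} (p = {res.p_value:.3f})"
)
print("a non-significant p means the 15:1 duplicate-recessive ratio fits")
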