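#!/usr/bin/env python
"""Map the genetic architecture of a simulated large-effect trait.

Runs permutation-thresholded stepwise main-QTL mapping and the stepwise
additive+epistatic (SPAEML-style) search on one simulated trait, compares
the result with the simulator's truth, and writes both QTL tables.
"""

import argparse
from pathlib import Path

import numpy as np

import magicgs as mg

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--permutations", type=int, default=1000)
ap.add_argument("--out", type=Path, default=Path("results"))
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

geno = mg.simulate_magic_panel(n_rils=305, n_snps_per_chr=100, n_chr=11,
                               seed=args.seed)
arch = mg.simulate.large_effect_architecture(geno, seed=args.seed + 1)
pt = mg.simulate_phenotypes(geno, arch, seed=args.seed + 2)
y = pt.values_for(geno.ril_ids, environment="env1")

true_large = [geno.snp_ids[j] for j, _ in arch.additive_qtl[:3]]
print("true large-effect QTL:", ", ".join(true_large))

main = mg.stepwise_main_qtl(geno, y, n_permutations=args.permutations,
                            seed=args.seed)
print(f"\nstepwise main-QTL model: {len(main.additive_terms)} loci "
      f"(entry threshold {main.permutation_threshold:.2e})")
print(main.additive_terms[["snp_id", "effect", "p", "pve"]]
      .round(4).to_string(index=False))
main.write_csv(args.out / "main_qtl.csv")

full = mg.spaeml_fit(geno, y, candidate_cap=50)
cls = full.snp_classification()
print(f"\nadditive+epistatic model: {len(full.additive_terms)} additive, "
      f"{len(full.epistatic_terms)} epistatic terms")
for snp, label in sorted(cls.items()):
    print(f"  {snp}: {label}")
full.write_csv(args.out / "additive_epistatic_qtl.csv")

found = sum(s in set(main.additive_terms["snp_id"]) for s in true_large)
print(f"\n{found}/3 true large QTL recovered exactly by the main scan "
      "(near hits within a few cM count in the formal studies)")
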