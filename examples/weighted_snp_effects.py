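"""Iteratively weighted ssGBLUP: SNP effects, weights, variance shares.

Runs three rounds of the weighted single-step loop on an oligogenic trait,
prints the per-iteration accuracy for the young candidates, and shows how
much of the marker variance the top SNPs capture.
"""

import numpy as np

from ssgblup import ModelSpec, VarianceComponents, make_partial_dataset, run_wssgblup, snp_set_overlap, top_snp_set
from ssgblup.simulate import SimulationConfig, simulate_population

pop = simulate_population(SimulationConfig(
    n_founders=400, n_generations=5, n_snps=800, n_qtl=30,
    heritability=0.4, qtl_effect_distribution="gamma-signed",
    genotyped_fraction_by_generation=[0, 0, 0, 0.5, 0.5], seed=11))

gen = pop.meta["generation"].to_numpy()
candidates = [a for a in pop.genotyped_ids
              if a in set(pop.meta.loc[gen == gen.max(), "id"])]
scen = make_partial_dataset(pop.phenotypes, pop.pedigree, candidates)
vc = VarianceComponents(pop.sigma2_a, pop.sigma2_e)

solve, effects, trace = run_wssgblup(
    ModelSpec("trait", ("cg", "sex")), scen.partial_data, scen.partial_pedigree,
    pop.genotyped_matrix(), vc, n_iterations=3,
    truth=pop.true_breeding_values, eval_ids=candidates)

print(trace.to_frame().round(4).to_string(index=False))

top = top_snp_set(effects.variance_share, 0.05)
qtl = set(int(j) for j in pop.qtl_indices)
print(f"\nSNPs explaining 5% of marker variance: {len(top)}")
print(f"of which designated QTL: {len(set(top) & qtl)} (QTL in panel: {len(qtl)})")

# compare the top-5% sets of iterations 2 and 3
_, eff2, _ = run_wssgblup(
    ModelSpec("trait", ("cg", "sex")), scen.partial_data, scen.partial_pedigree,
    pop.genotyped_matrix(), vc, n_iterations=2)
sets = [set(top_snp_set(eff2.variance_share, 0.05)), set(top)]
print("top-set overlap (iteration 2 vs 3):", snp_set_overlap(sets))

# Iteration 1 is plain ssGBLUP (all weights 1). The nonlinear weights
# concentrate on markers tracking real QTL, which lifts candidate accuracy
# at iterations 2-3; the overlap shows the top set is stable across rounds.
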