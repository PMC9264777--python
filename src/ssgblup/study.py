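"""End-to-end study designs on simulated populations.

These functions wire the generator, the three evaluation methods and the
forward-validation protocol into the experiments the package is built
around: method-accuracy comparison (pedigree BLUP vs ssGBLUP vs iteratively
weighted ssGBLUP), REML parameter recovery, and reference-group scenario
comparisons. They are what the example scripts and the acceptance runner
call.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .mme import (ModelSpec, TraitDataset, VarianceComponents,
                  estimate_variance_components, parent_average,
                  run_pedigree_blup)
from .pedigree import build_A_inverse
from .simulate import SimulationConfig, SimulatedPopulation, simulate_population
from .validation import make_partial_dataset, validation_metrics
from .wssgblup import run_wssgblup


def prediction_config(seed: int, *, n_qtl: int = 30, heritability: float = 0.4,
                      n_founders: int = 1000, n_generations: int = 5,
                      n_snps: int = 1000,
                      qtl_effect_distribution: str = "gamma-signed") -> SimulationConfig:
    """Forward-prediction design: last two generations half-genotyped.

    Defaults give 5 discrete generations of ~1000 animals (5000 total) with
    ~1000 genotyped, an oligogenic trait (30 QTL) at h2 = 0.4.
    """
    return SimulationConfig(
        n_founders=n_founders,
        n_generations=n_generations,
        offspring_per_mating=2,
        n_snps=n_snps,
        n_qtl=n_qtl,
        qtl_effect_distribution=qtl_effect_distribution,
        heritability=heritability,
        genotyped_fraction_by_generation=[0.0] * (n_generations - 2) + [0.5, 0.5],
        seed=seed,
    )


def compare_methods(config: SimulationConfig, n_iterations: int = 3,
                    pop: Optional[SimulatedPopulation] = None) -> dict:
    """Accuracy of PA / pedigree BLUP / ssGBLUP / wssGBLUP for young candidates.

    The validated set is the genotyped part of the final generation; their
    phenotypes are removed with the partial-data protocol (genotypes stay in
    the reference group) and every method predicts their true breeding
    values. Accuracies are Pearson correlations with TBV over that set.
    """
    if pop is None:
        pop = simulate_population(config)
    gen = pop.meta["generation"].to_numpy()
    last = gen.max()
    final_gen_ids = set(pop.meta.loc[gen == last, "id"].astype(str))
    validated = [a for a in pop.genotyped_ids if a in final_gen_ids]
    if len(validated) < 10:
        raise ValueError("too few genotyped final-generation animals to validate")

    scen = make_partial_dataset(pop.phenotypes, pop.pedigree, validated,
                                reference_ids=pop.genotyped_ids)
    vc = VarianceComponents(pop.sigma2_a, pop.sigma2_e)
    model = ModelSpec("trait", ("cg", "sex"))
    tbv = pop.true_breeding_values

    blup = run_pedigree_blup(model, scen.partial_data, scen.partial_pedigree, vc,
                             compute_pev=False)
    pa = parent_average(blup, scen.partial_pedigree)

    gm = pop.genotyped_matrix()
    solve, effects, trace = run_wssgblup(
        model, scen.partial_data, scen.partial_pedigree, gm, vc,
        n_iterations=n_iterations, compute_pev=False,
        truth=tbv, eval_ids=validated)

    t = tbv.loc[validated].to_numpy()

    def acc(series: pd.Series) -> float:
        return float(np.corrcoef(series.loc[validated].to_numpy(), t)[0, 1])

    out = {
        "n_animals": pop.pedigree.n,
        "n_genotyped": len(pop.genotyped_ids),
        "n_validated": len(validated),
        "acc_pa": acc(pa),
        "acc_blup": acc(blup.u_hat),
        "acc_ssgblup": trace.accuracy(1),
    }
    for it in range(2, n_iterations + 1):
        out[f"acc_wssgblup_iter{it}"] = trace.accuracy(it)
    out["trace"] = trace
    out["snp_effects"] = effects
    out["population"] = pop
    out["validated_ids"] = validated
    out["gebv_partial"] = solve.u_hat
    out["ebv_partial"] = blup.u_hat
    out["pa_partial"] = pa
    return out


def reml_recovery(seed: int, heritability: float, *, n_founders: int = 400,
                  n_generations: int = 5, n_snps: int = 1000,
                  n_qtl: int = 1000) -> float:
    """Estimate h2 by EM-REML on one simulated population; returns h2-hat.

    Fully polygenic architecture (every SNP causal, gaussian effects): with
    few QTL the realized relationships at the causal loci scatter around the
    pedigree expectation A (variance ~ 1/n_qtl) and an A-based REML absorbs
    that extra family resemblance into sigma2_a. A polygenic trait is the
    regime where the animal model's normality assumption holds.
    """
    cfg = SimulationConfig(
        n_founders=n_founders, n_generations=n_generations,
        offspring_per_mating=2, n_snps=n_snps, n_qtl=n_qtl,
        qtl_effect_distribution="gaussian", heritability=heritability,
        seed=seed,
    )
    pop = simulate_population(cfg)
    model = ModelSpec("trait", ("cg", "sex"))
    vc = estimate_variance_components(model, pop.phenotypes, pop.pedigree,
                                      build_A_inverse(pop.pedigree))
    return vc.h2


def validation_summary(config: SimulationConfig) -> dict:
    """PA vs genomic prediction of TBV, plus the inflation regression.

    Runs the forward-validation protocol once and reports correlation with
    truth for PA and ssGBLUP predictions of the validated animals, plus the
    dispersion slope of TBV on each prediction.
    """
    res = compare_methods(config, n_iterations=1)
    pop: SimulatedPopulation = res["population"]
    validated = res["validated_ids"]
    tbv = pop.true_breeding_values.loc[validated]
    pa = res["pa_partial"].loc[validated]
    gebv = res["gebv_partial"].loc[validated]
    return {
        "acc_pa": res["acc_pa"],
        "acc_gebv": res["acc_ssgblup"],
        "metrics_pa": validation_metrics(pa, tbv),
        "metrics_gebv": validation_metrics(gebv, tbv),
    }
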