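"""Synthetic livestock populations with known genetic truth.

Generates a multi-generation, discrete-generation pedigree under random
mating, drops biallelic SNP genotypes down the pedigree by Mendelian
sampling (unlinked loci: chromosome labels are kept in the marker map, but
no recombination map is simulated — QTL are a designated subset of the
genotyped SNPs, so marker-QTL association is exact by identity), assigns
QTL effects, and simulates phenotypes with contemporary-group and sex fixed
effects at a chosen heritability.

Everything downstream of the generator (relationship matrices, single-step
solves, SNP weighting, validation) can therefore be checked against the
true breeding values. The generator emulates the structure of a pig
breeding dataset: thousands of animals, a genotyped subset of several
hundred to ~1500 formed in nested stages (reference groups), heritabilities
in the 0.1-0.45 range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .mme import TraitDataset
from .pedigree import UNKNOWN, Pedigree
from .qc import GenotypeMatrix, MarkerMap


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Population, genome and trait architecture settings.

    ``genotyped_fraction_by_generation`` gives, per generation (founders
    first), the fraction of animals genotyped; the default genotypes half of
    the last two generations, mimicking genotyping campaigns that start late
    in a pedigree. ``scenario_cutoffs`` are generation numbers (1-based):
    scenario k contains the genotyped animals born up to the k-th cutoff,
    producing nested reference groups.
    """

    n_founders: int = 200
    n_generations: int = 5
    offspring_per_mating: int = 2
    n_snps: int = 1000
    n_chromosomes: int = 18
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int = 100
    qtl_effect_distribution: str = "gamma-signed"  # gaussian | gamma-signed | equal
    heritability: float = 0.3
    n_contemporary_groups: int = 5
    cg_effect_sd: float = 0.5
    sex_effect: float = 0.25
    genotyped_fraction_by_generation: Optional[list[float]] = None
    scenario_cutoffs: Optional[list[int]] = None
    mu: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_founders", "n_generations", "offspring_per_mating",
                     "n_snps", "n_chromosomes", "n_qtl", "n_contemporary_groups"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be >= 1")
        if not 0.0 < self.heritability < 1.0:
            raise SimulationError("heritability must be strictly inside (0,1)")
        if self.n_qtl > self.n_snps:
            raise SimulationError("n_qtl cannot exceed n_snps")
        lo, hi = self.founder_maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise SimulationError("founder_maf_range must satisfy 0 < low <= high < 1")
        if self.qtl_effect_distribution not in ("gaussian", "gamma-signed", "equal"):
            raise SimulationError(
                f"unknown qtl_effect_distribution {self.qtl_effect_distribution!r}")
        if self.genotyped_fraction_by_generation is None:
            f = [0.0] * self.n_generations
            for g in range(max(0, self.n_generations - 2), self.n_generations):
                f[g] = 0.5
            self.genotyped_fraction_by_generation = f
        if len(self.genotyped_fraction_by_generation) != self.n_generations:
            raise SimulationError(
                "genotyped_fraction_by_generation must have one entry per generation")
        if any(not 0.0 <= f <= 1.0 for f in self.genotyped_fraction_by_generation):
            raise SimulationError("genotyped fractions must lie in [0,1]")
        if self.scenario_cutoffs is None:
            self.scenario_cutoffs = [self.n_generations]
        if any(not 1 <= c <= self.n_generations for c in self.scenario_cutoffs):
            raise SimulationError("scenario cutoffs must be generation numbers (1-based)")
        if sorted(self.scenario_cutoffs) != list(self.scenario_cutoffs):
            raise SimulationError("scenario cutoffs must be nondecreasing (nested groups)")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        extra = set(raw) - known
        if extra:
            raise SimulationError(f"unknown simulation config keys: {sorted(extra)}")
        if "founder_maf_range" in raw:
            raw["founder_maf_range"] = tuple(raw["founder_maf_range"])
        return cls(**raw)

    def to_yaml(self, path):
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["founder_maf_range"] = list(d["founder_maf_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class SimulatedPopulation:
    pedigree: Pedigree
    genotypes: GenotypeMatrix  # all pedigree animals (rows in pedigree order)
    marker_map: MarkerMap
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    true_breeding_values: pd.Series  # indexed by animal id
    phenotypes: TraitDataset
    genotyped_ids_by_scenario: list[list[str]]
    meta: pd.DataFrame  # id, generation (1-based), sex, cg
    sigma2_a: float  # realized TBV variance
    sigma2_e: float  # residual variance used for the noise draw

    @property
    def genotyped_ids(self) -> list[str]:
        return self.genotyped_ids_by_scenario[-1]

    def genotyped_matrix(self, scenario: int = -1) -> GenotypeMatrix:
        """Genotype rows of one reference-group scenario (default: largest)."""
        return self.genotypes.subset(animal_ids=self.genotyped_ids_by_scenario[scenario])


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _structure(config: SimulationConfig):
    """Pedigree skeleton plus generation and sex labels (internal)."""
    rng = _rng(config, 0)
    ids: list[str] = []
    sire: list[int] = []
    dam: list[int] = []
    gen: list[int] = []
    sex: list[str] = []

    def add(g, s, d, sx):
        ids.append(str(len(ids) + 1))
        sire.append(s)
        dam.append(d)
        gen.append(g)
        sex.append(sx)

    for i in range(config.n_founders):
        add(1, UNKNOWN, UNKNOWN, "M" if i % 2 == 0 else "F")

    start = 0
    for g in range(2, config.n_generations + 1):
        prev = [i for i in range(len(ids)) if gen[i] == g - 1]
        males = [i for i in prev if sex[i] == "M"]
        females = [i for i in prev if sex[i] == "F"]
        if not males or not females:
            raise SimulationError(
                f"generation {g-1} lacks one sex; increase its size")
        females = list(rng.permutation(females))
        n_new = len(females) * config.offspring_per_mating
        # balanced sexes in random order: keeps cohort sizes stable across
        # generations (random 50/50 draws let them drift like a random walk)
        half = n_new // 2
        sexes = ["M"] * half + ["F"] * (n_new - half)
        sexes = [sexes[i] for i in rng.permutation(n_new)]
        if g < config.n_generations and n_new >= 2 and len(set(sexes)) == 1:
            sexes[0] = "M" if sexes[0] == "F" else "F"
        k = 0
        for f in females:
            m = males[int(rng.integers(len(males)))]
            for _ in range(config.offspring_per_mating):
                add(g, m, f, sexes[k])
                k += 1
    ped = Pedigree(ids, np.array(sire), np.array(dam))
    return ped, np.array(gen), np.array(sex, dtype=object)


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Discrete-generation random-mating pedigree.

    Founders have unknown parents; every non-founder's sire and dam come
    from the previous generation (each female of a generation is mated once
    to a randomly drawn male, producing ``offspring_per_mating`` offspring).
    """
    ped, _, _ = _structure(config)
    return ped


def drop_genes(pedigree: Pedigree, config: SimulationConfig) -> GenotypeMatrix:
    """Gene-drop genotypes for every pedigree animal (unlinked loci).

    Founder alleles are Bernoulli draws at per-locus frequencies uniform in
    ``founder_maf_range``; each offspring inherits one allele per locus from
    each parent, chosen by a fair coin independently across loci.
    """
    if not pedigree.is_sorted():
        raise SimulationError("pedigree must be sorted (parents first) for gene dropping")
    rng = _rng(config, 1)
    n, m = pedigree.n, config.n_snps
    freqs = rng.uniform(*config.founder_maf_range, size=m)
    hap1 = np.zeros((n, m), dtype=np.uint8)
    hap2 = np.zeros((n, m), dtype=np.uint8)
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            hap1[i] = rng.random(m) < freqs
            hap2[i] = rng.random(m) < freqs
            continue
        if s == UNKNOWN or d == UNKNOWN:
            raise SimulationError(
                f"animal {pedigree.ids[i]!r} has exactly one known parent; "
                "gene dropping expects founders or full trios")
        coin_s = rng.integers(0, 2, m).astype(bool)
        coin_d = rng.integers(0, 2, m).astype(bool)
        hap1[i] = np.where(coin_s, hap1[s], hap2[s])
        hap2[i] = np.where(coin_d, hap1[d], hap2[d])
    dosages = (hap1 + hap2).astype(float)
    snp_ids = [f"snp{j+1}" for j in range(m)]
    return GenotypeMatrix(dosages, list(pedigree.ids), snp_ids)


def make_marker_map(config: SimulationConfig) -> MarkerMap:
    """Markers spread evenly over the chromosomes, 1-based positions."""
    m = config.n_snps
    chrom = (np.arange(m) % config.n_chromosomes) + 1
    order = np.argsort(chrom, kind="stable")
    pos = np.zeros(m, dtype=int)
    for c in range(1, config.n_chromosomes + 1):
        w = np.flatnonzero(chrom[order] == c)
        pos[w] = np.arange(len(w)) * 100_000 + 1
    frame = pd.DataFrame({
        "chrom": chrom[order],
        "snp_id": [f"snp{j+1}" for j in order],
        "cm": 0.0,
        "pos": pos,
    })
    # keep snp column order aligned with the genotype matrix
    frame = frame.set_index("snp_id").loc[[f"snp{j+1}" for j in range(m)]].reset_index()
    return MarkerMap(frame[["chrom", "snp_id", "cm", "pos"]])


def assign_qtl(genotypes: GenotypeMatrix, config: SimulationConfig):
    """Pick QTL among the SNPs, draw effects, scale to the target variance.

    Effects are drawn once and rescaled so the realized variance of the true
    breeding values equals ``heritability`` (phenotypic variance is then ~1
    by construction). TBV_i = sum over QTL of centered dosage x effect.
    """
    rng = _rng(config, 2)
    qtl = np.sort(rng.choice(config.n_snps, size=config.n_qtl, replace=False))
    if config.qtl_effect_distribution == "gaussian":
        eff = rng.standard_normal(config.n_qtl)
    elif config.qtl_effect_distribution == "gamma-signed":
        eff = rng.gamma(0.4, 1.0, config.n_qtl) * rng.choice([-1.0, 1.0], config.n_qtl)
    else:  # equal magnitudes, random signs
        eff = rng.choice([-1.0, 1.0], config.n_qtl)
    p = genotypes.allele_frequencies()[qtl]
    Mq = genotypes.dosages[:, qtl] - 2.0 * p
    tbv = Mq @ eff
    v = float(np.var(tbv))
    if v <= 0.0:
        raise SimulationError("true breeding values have zero variance; "
                              "QTL monomorphic or effects all zero")
    scale = np.sqrt(config.heritability / v)
    return qtl, eff * scale, pd.Series(tbv * scale, index=list(genotypes.animal_ids))


def simulate_phenotypes(tbv: pd.Series, meta: pd.DataFrame,
                        config: SimulationConfig) -> tuple[TraitDataset, float]:
    """phenotype = mu + CG effect + sex effect + TBV + residual.

    The residual variance is set from the realized TBV variance so that the
    realized heritability matches the target:
    Var(e) = Var(TBV)(1-h^2)/h^2. Returns the dataset and the residual
    variance used. The ``weight`` column is a nuisance covariate (no effect
    on the trait).
    """
    rng = _rng(config, 3)
    var_a = float(np.var(tbv.to_numpy()))
    if var_a <= 0.0:
        raise SimulationError("zero TBV variance; cannot set the residual scale")
    h2 = config.heritability
    sigma2_e = var_a * (1.0 - h2) / h2
    n = len(tbv)
    cg_levels = sorted(meta["cg"].unique())
    cg_eff = pd.Series(rng.normal(0.0, config.cg_effect_sd, len(cg_levels)),
                       index=cg_levels)
    sex_eff = np.where(meta["sex"].to_numpy() == "M",
                       0.5 * config.sex_effect, -0.5 * config.sex_effect)
    eps = rng.normal(0.0, np.sqrt(sigma2_e), n)
    y = (config.mu + cg_eff.loc[meta["cg"]].to_numpy() + sex_eff
         + tbv.to_numpy() + eps)
    frame = pd.DataFrame({
        "id": meta["id"].astype(str),
        "cg": meta["cg"],
        "sex": meta["sex"],
        "weight": np.round(rng.normal(100.0, 10.0, n), 2),
        "trait": y,
    })
    return TraitDataset(frame), sigma2_e


def simulate_population(config: SimulationConfig) -> SimulatedPopulation:
    """Full synthetic population: pedigree, genotypes, QTL, phenotypes, scenarios."""
    ped, gen, sex = _structure(config)
    genotypes = drop_genes(ped, config)
    marker_map = make_marker_map(config)
    qtl, effects, tbv = assign_qtl(genotypes, config)

    rng = _rng(config, 4)
    cg = np.array([f"g{g}c{rng.integers(config.n_contemporary_groups) + 1}"
                   for g in gen])
    meta = pd.DataFrame({"id": ped.ids, "generation": gen, "sex": sex, "cg": cg})
    phenotypes, sigma2_e = simulate_phenotypes(tbv, meta, config)

    rng_g = _rng(config, 5)
    genotyped = np.zeros(ped.n, dtype=bool)
    for g in range(1, config.n_generations + 1):
        frac = config.genotyped_fraction_by_generation[g - 1]
        members = np.flatnonzero(gen == g)
        k = int(round(frac * len(members)))
        if k:
            chosen = rng_g.choice(members, size=k, replace=False)
            genotyped[chosen] = True
    scenarios = []
    for cutoff in config.scenario_cutoffs:
        sel = genotyped & (gen <= cutoff)
        scenarios.append([ped.ids[i] for i in np.flatnonzero(sel)])
    if not scenarios[-1]:
        raise SimulationError("no genotyped animals; raise the genotyped fractions")

    return SimulatedPopulation(
        pedigree=ped,
        genotypes=genotypes,
        marker_map=marker_map,
        qtl_indices=qtl,
        qtl_effects=effects,
        true_breeding_values=tbv,
        phenotypes=phenotypes,
        genotyped_ids_by_scenario=scenarios,
        meta=meta,
        sigma2_a=float(np.var(tbv.to_numpy())),
        sigma2_e=sigma2_e,
    )
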