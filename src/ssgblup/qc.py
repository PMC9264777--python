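"""Genotype container and quality control.

Dosage matrix (animals x SNPs, entries 0/1/2, NaN = missing) with allele
frequencies, centering, and the fixed-order QC pipeline used before building
a genomic relationship matrix:

    animal call rate -> SNP call rate -> MAF -> HWE -> Mendelian conflicts

followed by mean imputation (2p) of residual missing calls. The filter order
is pinned so QC reports are reproducible. An array-intensity (GC/GT score)
filter cannot be applied to dosage data and is recorded as not applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import UNKNOWN, Pedigree


class QCError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Animals x SNPs dosage matrix; entries in {0,1,2}, NaN = missing."""

    dosages: np.ndarray
    animal_ids: list[str]
    snp_ids: list[str]

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise QCError("dosage matrix must be 2-dimensional (animals x SNPs)")
        n, m = self.dosages.shape
        if n != len(self.animal_ids) or m != len(self.snp_ids):
            raise QCError("dosage matrix shape does not match id lists")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        # imputed matrices carry fractional values; only validate fresh input
        # when all entries are near-integers
        self._integral = bool(ok.all())

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())

    def allele_frequencies(self) -> np.ndarray:
        return allele_frequencies(self)

    def subset(self, animal_ids: Optional[Sequence[str]] = None,
               snp_idx: Optional[np.ndarray] = None) -> "GenotypeMatrix":
        d = self.dosages
        aids = self.animal_ids
        sids = self.snp_ids
        if animal_ids is not None:
            index = {a: i for i, a in enumerate(self.animal_ids)}
            try:
                rows = [index[a] for a in animal_ids]
            except KeyError as e:
                raise QCError(f"unknown animal id {e.args[0]!r}") from None
            d = d[rows, :]
            aids = list(animal_ids)
        if snp_idx is not None:
            d = d[:, snp_idx]
            sids = [self.snp_ids[j] for j in np.atleast_1d(snp_idx)]
        return GenotypeMatrix(d.copy(), list(aids), list(sids))

    def centered(self, freqs: Optional[np.ndarray] = None) -> np.ndarray:
        """Centered matrix M = dosages - 2p; requires no missing calls."""
        if self.has_missing():
            raise QCError("centered matrix requires imputed genotypes (missing calls present)")
        p = self.allele_frequencies() if freqs is None else np.asarray(freqs, float)
        return self.dosages - 2.0 * p

    def imputed(self, freqs: Optional[np.ndarray] = None) -> "GenotypeMatrix":
        """Fill missing calls with the mean dosage 2p per SNP."""
        p = self.allele_frequencies() if freqs is None else np.asarray(freqs, float)
        d = self.dosages.copy()
        miss = np.isnan(d)
        d[miss] = np.broadcast_to(2.0 * p, d.shape)[miss]
        return GenotypeMatrix(d, list(self.animal_ids), list(self.snp_ids))


@dataclass
class MarkerMap:
    """Per-SNP chromosome, identifier and base-pair position (1-based)."""

    frame: pd.DataFrame  # columns: chrom, snp_id, cm, pos

    def __post_init__(self):
        need = {"chrom", "snp_id", "pos"}
        if not need.issubset(self.frame.columns):
            raise QCError(f"marker map needs columns {sorted(need)}")
        if "cm" not in self.frame.columns:
            self.frame = self.frame.assign(cm=0.0)
        if (self.frame["pos"] < 1).any():
            raise QCError("marker positions must be >= 1")

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, snp_ids: Sequence[str]) -> "MarkerMap":
        f = self.frame.set_index("snp_id").loc[list(snp_ids)].reset_index()
        return MarkerMap(f[["chrom", "snp_id", "cm", "pos"]])


@dataclass
class QCThresholds:
    """Filter settings; fractions in [0,1], HWE threshold a probability."""

    animal_missing_max: float = 0.10
    snp_missing_max: float = 0.10
    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    hwe_min_calls: int = 10
    mendel_rate_max: float = 0.01

    def __post_init__(self):
        for name in ("animal_missing_max", "snp_missing_max", "maf_min",
                     "hwe_p_min", "mendel_rate_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise QCError(f"threshold {name}={v} outside [0,1]")


@dataclass
class QCReport:
    """Removal counts per filter, in application order."""

    initial_animals: int
    initial_snps: int
    steps: list[tuple[str, str, int]] = field(default_factory=list)  # (filter, axis, n_removed)
    final_animals: int = 0
    final_snps: int = 0
    notes: list[str] = field(default_factory=list)

    def removed(self, name: str) -> int:
        for step, _, k in self.steps:
            if step == name:
                return k
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["filter", "axis", "n_removed"])

    def check_consistent(self) -> bool:
        da = sum(k for _, ax, k in self.steps if ax == "animals")
        dm = sum(k for _, ax, k in self.steps if ax == "snps")
        return (self.initial_animals - da == self.final_animals
                and self.initial_snps - dm == self.final_snps)

    def __str__(self) -> str:
        lines = [f"QC: {self.initial_animals} animals x {self.initial_snps} SNPs in"]
        for step, axis, k in self.steps:
            lines.append(f"  {step:<18s} removed {k} {axis}")
        lines.append(f"  -> {self.final_animals} animals x {self.final_snps} SNPs")
        lines.extend(f"  note: {n}" for n in self.notes)
        return "\n".join(lines)


def allele_frequencies(genotypes: GenotypeMatrix) -> np.ndarray:
    """Counted-allele frequency p_i = mean dosage / 2 over non-missing calls."""
    d = genotypes.dosages
    called = (~np.isnan(d)).sum(axis=0)
    if (called == 0).any():
        j = int(np.argmax(called == 0))
        raise QCError(f"SNP {genotypes.snp_ids[j]!r} has no called genotypes")
    with np.errstate(invalid="ignore"):
        return np.nanmean(d, axis=0) / 2.0


def _genotype_counts(column: np.ndarray) -> tuple[int, int, int]:
    """Counts of hom-ref/het/hom-alt among exact integer calls.

    Fractional (imputed) values are not genotype calls and are ignored.
    """
    c = np.asarray(column, float)
    n0 = int(np.sum(np.abs(c - 0.0) < 1e-9))
    n1 = int(np.sum(np.abs(c - 1.0) < 1e-9))
    n2 = int(np.sum(np.abs(c - 2.0) < 1e-9))
    return n0, n1, n2


def hwe_test(column: np.ndarray, min_calls: int = 10) -> float:
    """Chi-square (1 df) goodness-of-fit p-value for Hardy-Weinberg.

    Observed genotype counts are compared with n*(q^2, 2pq, p^2) where p is
    the observed counted-allele frequency. Monomorphic columns fit their
    expectation exactly (p-value 1).
    """
    n0, n1, n2 = _genotype_counts(column)
    n = n0 + n1 + n2
    if n == 0:
        raise QCError("HWE test on a column with no called genotypes")
    if n < min_calls:
        raise QCError(f"HWE test needs >= {min_calls} calls, got {n}")
    p = (n1 + 2 * n2) / (2 * n)
    exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
    obs = np.array([n0, n1, n2], float)
    mask = exp > 0
    chi2 = float(np.sum((obs[mask] - exp[mask]) ** 2 / exp[mask]))
    return float(stats.chi2.sf(chi2, df=1))


def mendelian_conflict_rates(genotypes: GenotypeMatrix, pedigree: Pedigree) -> np.ndarray:
    """Per-animal max rate of opposite-homozygote conflicts with a genotyped parent.

    Only parent-offspring pairs where both are genotyped contribute; the rate
    is conflicts / co-called loci. Animals with no genotyped parent get 0.
    """
    index = {a: i for i, a in enumerate(genotypes.animal_ids)}
    d = genotypes.dosages
    rates = np.zeros(genotypes.n_animals)
    for row, animal in enumerate(genotypes.animal_ids):
        if animal not in pedigree.id_index:
            continue
        i = pedigree.id_index[animal]
        for par in (pedigree.sire[i], pedigree.dam[i]):
            if par == UNKNOWN:
                continue
            pid = pedigree.ids[par]
            if pid not in index:
                continue
            a, b = d[row], d[index[pid]]
            both = ~np.isnan(a) & ~np.isnan(b)
            n = int(both.sum())
            if n == 0:
                continue
            opp = np.sum(((a == 0) & (b == 2) | (a == 2) & (b == 0)) & both)
            rates[row] = max(rates[row], opp / n)
    return rates


def run_qc(genotypes: GenotypeMatrix,
           pedigree: Optional[Pedigree] = None,
           thresholds: QCThresholds = QCThresholds()) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the QC filters in fixed order and impute residual missing calls.

    Returns the cleaned, imputed genotype matrix and a report of removal
    counts per step. The Mendelian-conflict step needs a pedigree and is
    skipped (0 removals recorded) when none is given.
    """
    gm = genotypes
    report = QCReport(gm.n_animals, gm.n_snps)
    report.notes.append("GC/GT-score filter not applied (requires array intensities)")

    # 1. animal call rate
    miss = np.isnan(gm.dosages).mean(axis=1)
    keep = miss <= thresholds.animal_missing_max
    report.steps.append(("animal_call_rate", "animals", int((~keep).sum())))
    gm = gm.subset(animal_ids=[a for a, k in zip(gm.animal_ids, keep) if k])
    if gm.n_animals == 0:
        raise QCError("no animals left after animal call-rate filter")

    # 2. SNP call rate
    miss = np.isnan(gm.dosages).mean(axis=0)
    keep = miss <= thresholds.snp_missing_max
    report.steps.append(("snp_call_rate", "snps", int((~keep).sum())))
    gm = gm.subset(snp_idx=np.flatnonzero(keep))
    if gm.n_snps == 0:
        raise QCError("no SNPs left after SNP call-rate filter")

    # 3. minor allele frequency
    p = allele_frequencies(gm)
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= thresholds.maf_min
    report.steps.append(("maf", "snps", int((~keep).sum())))
    gm = gm.subset(snp_idx=np.flatnonzero(keep))
    if gm.n_snps == 0:
        raise QCError("no SNPs left after MAF filter")

    # 4. Hardy-Weinberg equilibrium (SNPs with too few calls are retained)
    keep = np.ones(gm.n_snps, dtype=bool)
    for j in range(gm.n_snps):
        counts = _genotype_counts(gm.dosages[:, j])
        if sum(counts) < thresholds.hwe_min_calls:
            continue
        if hwe_test(gm.dosages[:, j], thresholds.hwe_min_calls) < thresholds.hwe_p_min:
            keep[j] = False
    report.steps.append(("hwe", "snps", int((~keep).sum())))
    gm = gm.subset(snp_idx=np.flatnonzero(keep))
    if gm.n_snps == 0:
        raise QCError("no SNPs left after HWE filter")

    # 5. Mendelian conflicts: remove offspring whose conflict rate with a
    #    recorded genotyped parent exceeds the threshold
    if pedigree is not None:
        rates = mendelian_conflict_rates(gm, pedigree)
        keep = rates <= thresholds.mendel_rate_max
        report.steps.append(("mendelian", "animals", int((~keep).sum())))
        gm = gm.subset(animal_ids=[a for a, k in zip(gm.animal_ids, keep) if k])
        if gm.n_animals == 0:
            raise QCError("no animals left after Mendelian-conflict filter")
    else:
        report.steps.append(("mendelian", "animals", 0))
        report.notes.append("Mendelian filter skipped: no pedigree supplied")

    gm = gm.imputed()
    report.final_animals = gm.n_animals
    report.final_snps = gm.n_snps
    return gm, report
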