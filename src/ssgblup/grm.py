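"""Genomic relationship matrices and the single-step H-inverse blocks.

VanRaden's linear G = MM'/k with k = 2*sum(p_i(1-p_i)), the SNP-weighted
G* = M D M'/k, blending with the pedigree block A22 (G_b = alpha*G +
beta*A22), and the correction block

    Delta = tau * G_b^{-1} - omega * A22^{-1}

that turns the pedigree A-inverse into the single-step H-inverse when
scattered onto the genotyped animals' rows and columns. Defaults alpha=0.95,
beta=0.05, tau=omega=1.

Centering uses the observed allele frequencies of the current genotyped set
(base-population frequencies are unavailable in practice), and no further
rescaling of G toward A22 is applied. Dense algebra; genotyped-set sizes up
to a few thousand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.linalg as la
import scipy.sparse as sp

from .pedigree import RelationshipMatrix
from .qc import GenotypeMatrix


class GRMError(ValueError):
    pass


@dataclass
class HInverseParams:
    """Blending and scaling coefficients of the single-step H-inverse."""

    alpha: float = 0.95
    beta: float = 0.05
    tau: float = 1.0
    omega: float = 1.0

    def __post_init__(self):
        if abs(self.alpha + self.beta - 1.0) > 1e-10:
            raise GRMError(f"alpha + beta must equal 1, got {self.alpha + self.beta}")


@dataclass
class GenomicMatrix:
    """Symmetric genomic relationship matrix over the genotyped animals."""

    values: np.ndarray
    ids: list[str]
    k: float  # scaling constant 2*sum(p_i*(1-p_i))
    weighted: bool = False
    blended: bool = False

    @property
    def n(self) -> int:
        return len(self.ids)


def scaling_constant(freqs: np.ndarray) -> float:
    p = np.asarray(freqs, float)
    return float(2.0 * np.sum(p * (1.0 - p)))


def build_G(genotypes: GenotypeMatrix,
            weights: Optional[np.ndarray] = None,
            freqs: Optional[np.ndarray] = None) -> GenomicMatrix:
    """VanRaden G = MM'/k, or the weighted G* = M D M'/k.

    ``weights`` is the diagonal of D (length = number of SNPs). Genotypes
    must be QC'd and imputed (no missing calls).
    """
    p = genotypes.allele_frequencies() if freqs is None else np.asarray(freqs, float)
    k = scaling_constant(p)
    if k <= 0.0:
        raise GRMError("scaling constant 2*sum(p(1-p)) is zero: all SNPs monomorphic")
    M = genotypes.centered(p)
    if weights is None:
        G = (M @ M.T) / k
        weighted = False
    else:
        d = np.asarray(weights, float)
        if d.shape != (genotypes.n_snps,):
            raise GRMError(f"weight vector length {d.shape} != number of SNPs {genotypes.n_snps}")
        if (d < 0).any():
            raise GRMError("SNP weights must be nonnegative")
        G = ((M * d) @ M.T) / k
        weighted = True
    G = 0.5 * (G + G.T)
    return GenomicMatrix(G, list(genotypes.animal_ids), k, weighted=weighted)


def blend_G(G: GenomicMatrix, A22: RelationshipMatrix,
            params: HInverseParams = HInverseParams()) -> GenomicMatrix:
    """G_b = alpha*G + beta*A22; raises if the blend is not positive definite."""
    if list(A22.ids) != list(G.ids):
        raise GRMError("G and A22 animal orders differ; align ids before blending")
    Gb = params.alpha * G.values + params.beta * A22.dense()
    Gb = 0.5 * (Gb + Gb.T)
    w = la.eigvalsh(Gb, subset_by_index=(0, 0))
    scale = max(1.0, float(np.trace(Gb)) / max(1, Gb.shape[0]))
    if w[0] <= -1e-8 * scale:
        raise GRMError(
            f"blended genomic matrix not positive definite (min eigenvalue {w[0]:.3e}); "
            "increase beta")
    return GenomicMatrix(Gb, list(G.ids), G.k, weighted=G.weighted, blended=True)


def _sym_inverse(mat: np.ndarray, what: str) -> np.ndarray:
    try:
        c, low = la.cho_factor(mat, lower=True, check_finite=False)
    except la.LinAlgError as e:
        raise GRMError(f"{what} is singular or not positive definite") from e
    inv = la.cho_solve((c, low), np.eye(mat.shape[0]), check_finite=False)
    return 0.5 * (inv + inv.T)


def build_H_inverse_correction(G_b: GenomicMatrix, A22: RelationshipMatrix,
                               params: HInverseParams = HInverseParams()) -> RelationshipMatrix:
    """Delta = tau*G_b^{-1} - omega*A22^{-1} over the genotyped animals.

    The full H-inverse is the pedigree A-inverse plus Delta scattered onto
    the genotyped positions. With tau=omega=0, or when G_b equals A22 with
    tau=omega=1, Delta vanishes and H-inverse reduces to A-inverse.
    """
    if list(G_b.ids) != list(A22.ids):
        raise GRMError("G and A22 animal orders differ")
    n = G_b.n
    if n == 0:
        return RelationshipMatrix(np.zeros((0, 0)), "H_correction", [])
    delta = np.zeros((n, n))
    if params.tau != 0.0:
        delta += params.tau * _sym_inverse(G_b.values, "blended genomic matrix")
    if params.omega != 0.0:
        delta -= params.omega * _sym_inverse(A22.dense(), "A22")
    return RelationshipMatrix(0.5 * (delta + delta.T), "H_correction", list(G_b.ids))


def assemble_H_inverse(A_inv: RelationshipMatrix,
                       correction: RelationshipMatrix) -> RelationshipMatrix:
    """H^{-1} = A^{-1} + scatter(Delta) over the full pedigree, sparse."""
    if A_inv.kind != "A_inverse":
        raise GRMError(f"expected kind 'A_inverse', got {A_inv.kind!r}")
    index = {a: i for i, a in enumerate(A_inv.ids)}
    try:
        pos = np.array([index[g] for g in correction.ids], dtype=np.int64)
    except KeyError as e:
        raise GRMError(f"genotyped id {e.args[0]!r} not in pedigree A-inverse") from None
    n = A_inv.n
    base = A_inv.values if sp.issparse(A_inv.values) else sp.csr_matrix(A_inv.values)
    if len(pos) == 0:
        return RelationshipMatrix(base.copy(), "H_inverse", list(A_inv.ids))
    g = len(pos)
    rows = np.repeat(pos, g)
    cols = np.tile(pos, g)
    scatter = sp.coo_matrix((correction.dense().ravel(), (rows, cols)), shape=(n, n))
    H = (base + scatter.tocsr()).tocsr()
    return RelationshipMatrix(H, "H_inverse", list(A_inv.ids))
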