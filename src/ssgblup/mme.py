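"""Henderson's mixed-model equations for the single-trait animal model.

    y = Xb + Za + e,   a ~ N(0, K sigma2_a),   e ~ N(0, I sigma2_e)

where K is the relationship structure: the pedigree A for classic BLUP, or
the single-step H for ssGBLUP (the solver only ever sees K^{-1}). The
coefficient matrix is

    [[X'X, X'Z], [Z'X, Z'Z + lambda K^{-1}]],   lambda = sigma2_e/sigma2_a,

solved by a dense Cholesky factorization at desk scale (pedigrees up to a
few thousand animals; O(n^3)). Prediction error variances come from the
animal block of the inverse coefficient matrix, PEV_i = C^{uu}_ii*sigma2_e,
and reliability is Rel_i = 1 - PEV_i/sigma2_a, clipped to [0,1] and with no
inbreeding adjustment.

Variance components are estimated by EM-REML. A one-time generalized
eigendecomposition of (Z'SZ, K^{-1}) — S the fixed-effect projector — makes
every EM update O(q), so the slow-but-robust EM iteration is affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp

from .pedigree import UNKNOWN, Pedigree, RelationshipMatrix, build_A_inverse


class ModelError(ValueError):
    pass


@dataclass
class ModelSpec:
    """Fixed and random structure of the single-trait animal model.

    ``factors`` are categorical fixed effects (e.g. contemporary group, sex);
    ``covariates`` continuous ones (e.g. body weight). With ``intercept``
    the first level of every factor is dropped for identifiability; without
    it the first factor keeps all its levels.
    """

    trait: str
    factors: tuple[str, ...] = ("cg", "sex")
    covariates: tuple[str, ...] = ()
    intercept: bool = True
    relationship: str = "A_inverse"  # or "H_inverse"

    def __post_init__(self):
        self.factors = tuple(self.factors)
        self.covariates = tuple(self.covariates)


@dataclass
class TraitDataset:
    """One phenotype record per animal: id column plus model columns."""

    data: pd.DataFrame
    id_col: str = "id"

    def __post_init__(self):
        if self.id_col not in self.data.columns:
            raise ModelError(f"phenotype table lacks id column {self.id_col!r}")
        if self.data[self.id_col].duplicated().any():
            dup = self.data[self.id_col][self.data[self.id_col].duplicated()].iloc[0]
            raise ModelError(f"animal {dup!r} has more than one record")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def animal_ids(self) -> list[str]:
        return [str(a) for a in self.data[self.id_col]]


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_e: float

    def __post_init__(self):
        if self.sigma2_a <= 0 or self.sigma2_e <= 0:
            raise ModelError("variance components must be positive")

    @property
    def h2(self) -> float:
        return self.sigma2_a / (self.sigma2_a + self.sigma2_e)

    @property
    def lam(self) -> float:
        return self.sigma2_e / self.sigma2_a


@dataclass
class SolveResult:
    """Fixed-effect solutions, breeding values, PEV and reliability."""

    b_hat: pd.Series
    u_hat: pd.Series  # indexed by animal id, pedigree order
    pev: Optional[pd.Series]
    reliability: Optional[pd.Series]
    vc: VarianceComponents
    relationship: str = "A_inverse"


@dataclass
class MMESystem:
    C: np.ndarray
    rhs: np.ndarray
    X: np.ndarray
    Z: sp.csr_matrix
    y: np.ndarray
    effect_names: list[str]
    animal_ids: list[str]
    vc: VarianceComponents
    relationship: str = "A_inverse"

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]


def build_design(model: ModelSpec, data: TraitDataset,
                 pedigree: Pedigree) -> tuple[np.ndarray, sp.csr_matrix, np.ndarray, list[str]]:
    """Incidence matrices X (fixed) and Z (records -> pedigree animals)."""
    df = data.data
    if len(df) == 0:
        raise ModelError("empty phenotype dataset")
    if model.trait not in df.columns:
        raise ModelError(f"trait column {model.trait!r} missing from data")
    y = df[model.trait].to_numpy(dtype=float)

    cols: list[np.ndarray] = []
    names: list[str] = []
    if model.intercept:
        cols.append(np.ones(len(df)))
        names.append("intercept")
    for fi, fac in enumerate(model.factors):
        if fac not in df.columns:
            raise ModelError(f"factor column {fac!r} missing from data")
        levels = pd.unique(df[fac].astype(str))
        levels = sorted(levels)
        drop_first = model.intercept or fi > 0
        use = levels[1:] if drop_first else levels
        if drop_first and len(levels) < 2:
            raise ModelError(f"factor {fac!r} has a single level after reference dropping")
        vals = df[fac].astype(str).to_numpy()
        for lev in use:
            cols.append((vals == lev).astype(float))
            names.append(f"{fac}={lev}")
    for cov in model.covariates:
        if cov not in df.columns:
            raise ModelError(f"covariate column {cov!r} missing from data")
        cols.append(df[cov].to_numpy(dtype=float))
        names.append(cov)
    X = np.column_stack(cols) if cols else np.zeros((len(df), 0))
    if X.shape[1] and np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError(
            f"fixed effects are confounded (rank-deficient design over {list(model.factors)})")

    rec_pos = pedigree.positions(data.animal_ids)
    Z = sp.csr_matrix(
        (np.ones(len(df)), (np.arange(len(df)), rec_pos)),
        shape=(len(df), pedigree.n),
    )
    return X, Z, y, names


def assemble_mme(model: ModelSpec, data: TraitDataset, pedigree: Pedigree,
                 K_inv: RelationshipMatrix, vc: VarianceComponents) -> MMESystem:
    """Dense MME coefficient matrix and right-hand side."""
    if list(K_inv.ids) != list(pedigree.ids):
        raise ModelError("relationship inverse must span the pedigree in pedigree order")
    X, Z, y, names = build_design(model, data, pedigree)
    p, q = X.shape[1], pedigree.n
    lam = vc.lam

    C = np.zeros((p + q, p + q))
    if p:
        C[:p, :p] = X.T @ X
        XtZ = Z.T.dot(X).T  # p x q
        C[:p, p:] = XtZ
        C[p:, :p] = XtZ.T
    ZtZ = (Z.T @ Z).tocoo()
    C[p + ZtZ.row, p + ZtZ.col] += ZtZ.data
    Kv = K_inv.values
    Kcoo = Kv.tocoo() if sp.issparse(Kv) else sp.coo_matrix(Kv)
    np.add.at(C, (p + Kcoo.row, p + Kcoo.col), lam * Kcoo.data)

    rhs = np.concatenate([X.T @ y if p else np.zeros(0), Z.T @ y])
    return MMESystem(C, rhs, X, Z, y, names, list(pedigree.ids), vc, model.relationship)


def solve_mme(system: MMESystem, compute_pev: bool = True) -> SolveResult:
    """Direct symmetric solve; optionally PEV/reliability via the full inverse.

    PEV needs the animal-block diagonal of the inverse coefficient matrix,
    an extra O(n^3) step — skip it (``compute_pev=False``) when only breeding
    values are wanted.
    """
    p = system.n_fixed
    try:
        cf = la.cho_factor(system.C, lower=True, check_finite=False)
    except la.LinAlgError as e:
        raise ModelError(
            "singular mixed-model equations: fixed effects confounded or "
            f"relationship inverse not positive definite ({system.effect_names})") from e
    sol = la.cho_solve(cf, system.rhs, check_finite=False)
    b = pd.Series(sol[:p], index=system.effect_names, name="b_hat")
    u = pd.Series(sol[p:], index=system.animal_ids, name="u_hat")

    pev = rel = None
    if compute_pev:
        Cinv = la.cho_solve(cf, np.eye(system.C.shape[0]), check_finite=False)
        cuu = np.diag(Cinv)[p:]
        pev_v = cuu * system.vc.sigma2_e
        rel_v = np.clip(1.0 - pev_v / system.vc.sigma2_a, 0.0, 1.0)
        pev = pd.Series(pev_v, index=system.animal_ids, name="pev")
        rel = pd.Series(rel_v, index=system.animal_ids, name="reliability")
    return SolveResult(b, u, pev, rel, system.vc, system.relationship)


def run_animal_model(model: ModelSpec, data: TraitDataset, pedigree: Pedigree,
                     K_inv: RelationshipMatrix, vc: VarianceComponents,
                     compute_pev: bool = True) -> SolveResult:
    return solve_mme(assemble_mme(model, data, pedigree, K_inv, vc), compute_pev)


def run_pedigree_blup(model: ModelSpec, data: TraitDataset, pedigree: Pedigree,
                      vc: VarianceComponents, compute_pev: bool = True) -> SolveResult:
    """Classic animal-model BLUP with Henderson's A-inverse."""
    return run_animal_model(model, data, pedigree, build_A_inverse(pedigree), vc,
                            compute_pev)


def parent_average(result: SolveResult, pedigree: Pedigree) -> pd.Series:
    """PA_i = (u_sire + u_dam)/2; an unknown parent contributes 0."""
    u = result.u_hat.to_numpy()
    s, d = pedigree.sire, pedigree.dam
    us = np.where(s >= 0, u[np.maximum(s, 0)], 0.0)
    ud = np.where(d >= 0, u[np.maximum(d, 0)], 0.0)
    return pd.Series((us + ud) / 2.0, index=list(pedigree.ids), name="parent_average")


@dataclass
class REMLTrace:
    iterations: list[tuple[int, float, float]] = field(default_factory=list)

    def append(self, it: int, sa: float, se: float):
        self.iterations.append((it, sa, se))


class REMLConvergenceError(RuntimeError):
    def __init__(self, msg, trace: REMLTrace):
        super().__init__(msg)
        self.trace = trace


def estimate_variance_components(model: ModelSpec, data: TraitDataset,
                                 pedigree: Pedigree, K_inv: RelationshipMatrix,
                                 init: Optional[tuple[float, float]] = None,
                                 fix_sigma2_a: Optional[float] = None,
                                 tol: float = 1e-6,
                                 max_iter: int = 20000) -> VarianceComponents:
    """EM-REML for (sigma2_a, sigma2_e) in the animal model.

    EM updates:
        sigma2_a <- (u'K^{-1}u + sigma2_e * tr(K^{-1} C^{uu})) / q
                    with C^{uu} the animal block of the inverse MME
                    coefficient matrix,
        sigma2_e <- (y'y - b'X'y - u'Z'y) / (n - rank(X)),

    iterated until the relative change of both components is below ``tol``.
    After absorbing the fixed effects, the MME animal block is
    W + lambda*K^{-1} with W = Z'SZ; the generalized eigendecomposition
    W v = mu K^{-1} v (computed once) gives u'K^{-1}u and
    tr(K^{-1}C^{uu}) = sigma2_e * sum 1/(mu_j + lambda) in O(q) per
    iteration. EM needs thousands of rounds when the heritability is low;
    since each round is cheap after the eigendecomposition, the default
    iteration cap is generous. Desk scale: q up to ~5000 (dense q x q
    eigendecomposition).
    """
    if list(K_inv.ids) != list(pedigree.ids):
        raise ModelError("relationship inverse must span the pedigree in pedigree order")
    X, Z, y, _ = build_design(model, data, pedigree)
    n, p = X.shape
    q = pedigree.n

    if p:
        Q, _ = np.linalg.qr(X)  # n x p orthonormal basis of col(X)
        ZtQ = Z.T.dot(Q)  # q x p
        W = (Z.T @ Z).toarray() - ZtQ @ ZtQ.T
        r = Z.T @ y - ZtQ @ (Q.T @ y)
    else:
        W = (Z.T @ Z).toarray()
        r = Z.T @ y
    Kd = K_inv.values.toarray() if sp.issparse(K_inv.values) else np.asarray(K_inv.values, float)
    mu, V = la.eigh(0.5 * (W + W.T), 0.5 * (Kd + Kd.T))
    mu = np.maximum(mu, 0.0)  # W is PSD; clip eigenvalue noise
    c = V.T @ r

    XtX = X.T @ X if p else None
    Xty = X.T @ y if p else None
    XtZ = Z.T.dot(X).T if p else None  # p x q
    Zty = Z.T @ y
    yty = float(y @ y)

    vy = float(np.var(y))
    if init is None:
        sa = fix_sigma2_a if fix_sigma2_a is not None else 0.5 * vy
        se = 0.5 * vy
    else:
        sa, se = init
        if fix_sigma2_a is not None:
            sa = fix_sigma2_a

    trace = REMLTrace()
    for it in range(1, max_iter + 1):
        lam = se / sa
        denom = mu + lam
        u = V @ (c / denom)
        uKu = float(np.sum((c / denom) ** 2))
        tr_term = se * float(np.sum(1.0 / denom))  # tr(K^{-1} C^{uu})
        sa_new = fix_sigma2_a if fix_sigma2_a is not None else (uKu + tr_term) / q
        if p:
            bhat = la.solve(XtX, Xty - XtZ @ u, assume_a="pos")
            se_new = (yty - float(bhat @ Xty) - float(u @ Zty)) / (n - p)
        else:
            se_new = (yty - float(u @ Zty)) / n
        trace.append(it, sa_new, se_new)
        if se_new <= 0 or sa_new <= 0:
            raise REMLConvergenceError(
                f"EM-REML produced a non-positive variance at iteration {it}", trace)
        da = abs(sa_new - sa) / max(sa, 1e-12)
        de = abs(se_new - se) / max(se, 1e-12)
        sa, se = sa_new, se_new
        if da < tol and de < tol:
            return VarianceComponents(sa, se)
    raise REMLConvergenceError(
        f"EM-REML did not converge in {max_iter} iterations "
        f"(last sigma2_a={sa:.6g}, sigma2_e={se:.6g})", trace)
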