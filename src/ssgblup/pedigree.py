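"""Pedigree (numerator) relationship matrix machinery.

Builds the additive relationship matrix A by the tabular method, inbreeding
coefficients by the Meuwissen-Luo algorithm, Henderson's sparse A-inverse
(with inbreeding), and the genotyped block A22 used for blending with the
genomic relationship matrix.

Unknown parents are treated as unrelated, non-inbred base animals (no
unknown-parent groups). Ids are strings externally; after sorting, animals
are addressed by consecutive 0-based positions internally.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

UNKNOWN = -1
#: id tokens read as "parent unknown" in external records
UNKNOWN_TOKENS = {"", "0", ".", "NA", None}


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Ordered trio records (animal, sire, dam) with parents as positions.

    ``sire``/``dam`` hold 0-based positions into ``ids`` or ``UNKNOWN`` (-1).
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    _index: dict[str, int] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if len(self.ids) != len(set(self.ids)):
            raise PedigreeError("duplicate animal ids in pedigree")
        if len(self.sire) != len(self.ids) or len(self.dam) != len(self.ids):
            raise PedigreeError("parent arrays must match number of animals")

    @property
    def n(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return self.n

    @property
    def id_index(self) -> dict[str, int]:
        if self._index is None:
            self._index = {a: i for i, a in enumerate(self.ids)}
        return self._index

    def positions(self, ids: Iterable[str]) -> np.ndarray:
        idx = self.id_index
        try:
            return np.array([idx[a] for a in ids], dtype=np.int64)
        except KeyError as e:
            raise PedigreeError(f"unknown animal id {e.args[0]!r}") from None

    @classmethod
    def from_records(cls, records: Sequence[tuple[str, str, str]]) -> "Pedigree":
        """Build from (animal, sire, dam) string triples; '0'/'' = unknown.

        Every named parent must itself appear as an animal record.
        """
        ids = [str(r[0]) for r in records]
        index = {a: i for i, a in enumerate(ids)}
        if len(index) != len(ids):
            raise PedigreeError("duplicate animal ids in pedigree records")

        def parent(tok, animal):
            tok = None if tok is None else str(tok)
            if tok in UNKNOWN_TOKENS:
                return UNKNOWN
            if tok not in index:
                raise PedigreeError(
                    f"parent {tok!r} of animal {animal!r} has no pedigree record"
                )
            return index[tok]

        sire = np.array([parent(r[1], r[0]) for r in records], dtype=np.int64)
        dam = np.array([parent(r[2], r[0]) for r in records], dtype=np.int64)
        return cls(ids, sire, dam, index)

    def to_records(self) -> list[tuple[str, str, str]]:
        out = []
        for i, a in enumerate(self.ids):
            s = self.ids[self.sire[i]] if self.sire[i] >= 0 else "0"
            d = self.ids[self.dam[i]] if self.dam[i] >= 0 else "0"
            out.append((a, s, d))
        return out

    def is_sorted(self) -> bool:
        order = np.arange(self.n)
        ok_s = (self.sire < order) | (self.sire == UNKNOWN)
        ok_d = (self.dam < order) | (self.dam == UNKNOWN)
        return bool(np.all(ok_s) and np.all(ok_d))


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix with its animal-id ordering.

    ``values`` may be dense (ndarray) or scipy sparse; ``kind`` is one of
    {"A", "A_inverse", "A22", "A22_inverse", "H_inverse"}.
    """

    values: object
    kind: str
    ids: list[str]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return self.values.toarray()
        return np.asarray(self.values)

    @property
    def n(self) -> int:
        return len(self.ids)


def sort_pedigree(pedigree: Pedigree) -> Pedigree:
    """Topologically sort so every parent precedes its offspring.

    Stable: animals whose parents are already placed keep their relative
    input order. Raises :class:`PedigreeError` naming an offending animal if
    the pedigree contains a cycle (an animal that is its own ancestor).
    """
    n = pedigree.n
    placed = np.zeros(n, dtype=bool)
    order: list[int] = []
    remaining = list(range(n))
    while remaining:
        progressed = []
        still = []
        for i in remaining:
            s, d = pedigree.sire[i], pedigree.dam[i]
            if (s == UNKNOWN or placed[s]) and (d == UNKNOWN or placed[d]):
                progressed.append(i)
            else:
                still.append(i)
        if not progressed:
            raise PedigreeError(
                f"pedigree cycle: animal {pedigree.ids[still[0]]!r} is its own ancestor"
            )
        for i in progressed:
            placed[i] = True
            order.append(i)
        remaining = still

    pos = np.empty(n, dtype=np.int64)
    pos[order] = np.arange(n)
    ids = [pedigree.ids[i] for i in order]

    def remap(parents):
        out = np.full(n, UNKNOWN, dtype=np.int64)
        for new, old in enumerate(order):
            p = parents[old]
            out[new] = pos[p] if p != UNKNOWN else UNKNOWN
        return out

    return Pedigree(ids, remap(pedigree.sire), remap(pedigree.dam))


def _require_sorted(pedigree: Pedigree):
    if not pedigree.is_sorted():
        raise PedigreeError("pedigree must be topologically sorted (parents first); call sort_pedigree")


def build_A(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the recursive tabular method.

    a_ii = 1 + 0.5*a(sire,dam); a_ij = 0.5*(a(j,sire_i) + a(j,dam_i)) for
    j < i; an unknown parent contributes 0. Dense, O(n^2) memory — desk
    scale (n up to a few thousand).
    """
    _require_sorted(pedigree)
    n = pedigree.n
    A = np.zeros((n, n))
    sire, dam = pedigree.sire, pedigree.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        if i > 0:
            row = np.zeros(i)
            if s != UNKNOWN:
                row += A[s, :i]
            if d != UNKNOWN:
                row += A[d, :i]
            row *= 0.5
            A[i, :i] = row
            A[:i, i] = row
        asd = A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
    return RelationshipMatrix(A, "A", list(pedigree.ids))


def inbreeding(pedigree: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F by the Meuwissen-Luo algorithm.

    Avoids forming A: for each animal the diagonal a_ii = sum_j L_j^2 D_j is
    accumulated over its ancestor set, where D_j is the Mendelian-sampling
    variance coefficient of ancestor j. F_i = a_ii - 1.
    """
    _require_sorted(pedigree)
    n = pedigree.n
    sire, dam = pedigree.sire, pedigree.dam
    F = np.zeros(n)
    D = np.empty(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s != UNKNOWN and d != UNKNOWN:
            D[i] = 0.5 - 0.25 * (F[s] + F[d])
        elif s != UNKNOWN or d != UNKNOWN:
            p = s if s != UNKNOWN else d
            D[i] = 0.75 - 0.25 * F[p]
        else:
            D[i] = 1.0
        if s == UNKNOWN or d == UNKNOWN:
            # F stays 0: missing parent means an unrelated base contribution
            continue
        # walk the ancestor set of i in strictly decreasing index order
        # (parents always precede offspring in a sorted pedigree)
        aii = 0.0
        Lmap = {i: 1.0}
        heap = [-i]
        inheap = {i}
        while heap:
            j = -heapq.heappop(heap)
            lj = Lmap.pop(j)
            inheap.discard(j)
            aii += lj * lj * D[j]
            for p in (sire[j], dam[j]):
                if p != UNKNOWN:
                    Lmap[p] = Lmap.get(p, 0.0) + 0.5 * lj
                    if p not in inheap:
                        heapq.heappush(heap, -p)
                        inheap.add(p)
        F[i] = aii - 1.0
    return F


def build_A_inverse(pedigree: Pedigree) -> RelationshipMatrix:
    """Henderson's sparse A-inverse with inbreeding (Meuwissen-Luo F).

    For each animal i with Mendelian-sampling variance m_i, alpha = 1/m_i is
    added at (i,i), -alpha/2 at (i,parent), and alpha/4 among parents.
    Nonzeros therefore occur only within (animal, sire, dam) triples.
    """
    _require_sorted(pedigree)
    n = pedigree.n
    F = inbreeding(pedigree)
    sire, dam = pedigree.sire, pedigree.dam
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)
        if r != c:
            rows.append(c)
            cols.append(r)
            vals.append(v)

    for i in range(n):
        s, d = sire[i], dam[i]
        if s != UNKNOWN and d != UNKNOWN:
            m = 0.5 - 0.25 * (F[s] + F[d])
        elif s != UNKNOWN or d != UNKNOWN:
            p = s if s != UNKNOWN else d
            m = 0.75 - 0.25 * F[p]
        else:
            m = 1.0
        a = 1.0 / m
        add(i, i, a)
        for p in (s, d):
            if p != UNKNOWN:
                add(i, p, -0.5 * a)
        known = [p for p in (s, d) if p != UNKNOWN]
        for x in range(len(known)):
            for y in range(x, len(known)):
                add(known[x], known[y], 0.25 * a)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return RelationshipMatrix(Ainv, "A_inverse", list(pedigree.ids))


def subset_A22(A: RelationshipMatrix, genotyped_ids: Sequence[str]) -> RelationshipMatrix:
    """Extract the genotyped block of A, in the given (genotype-matrix) order."""
    if A.kind != "A":
        raise ValueError(f"expected kind 'A', got {A.kind!r}")
    index = {a: i for i, a in enumerate(A.ids)}
    try:
        pos = np.array([index[g] for g in genotyped_ids], dtype=np.int64)
    except KeyError as e:
        raise PedigreeError(f"genotyped id {e.args[0]!r} not in relationship matrix") from None
    vals = A.dense()[np.ix_(pos, pos)]
    return RelationshipMatrix(vals, "A22", list(genotyped_ids))


def invert_A22(A22: RelationshipMatrix) -> RelationshipMatrix:
    """Dense inverse of the (symmetric positive-definite) genotyped block."""
    if A22.kind != "A22":
        raise ValueError(f"expected kind 'A22', got {A22.kind!r}")
    vals = np.linalg.inv(A22.dense())
    vals = 0.5 * (vals + vals.T)
    return RelationshipMatrix(vals, "A22_inverse", list(A22.ids))
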