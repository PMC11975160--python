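"""Pedigree relationship machinery.

Implements the numerator relationship matrix A (tabular method), pedigree
inbreeding by the Meuwissen & Luo algorithm, Henderson's sparse inverse of
A with inbreeding, and efficient extraction of A sub-blocks through the
``A = T D T'`` decomposition (``T = (I - P)^{-1}`` with P the parent
contribution matrix, D the Mendelian-sampling variance diagonal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp
from numba import njit
from scipy.sparse.linalg import splu

__all__ = [
    "PedigreeTable",
    "inbreeding",
    "build_A",
    "build_A_inverse",
    "relationship_submatrix",
    "cohort_relationship",
]


@dataclass
class PedigreeTable:
    """Topologically ordered pedigree.

    ``sire``/``dam`` hold the *positions* of the parents inside this table
    (-1 = unknown); ``ids`` are the original animal labels.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    birth_cycle: Optional[np.ndarray] = None

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = self.ids.size
        if np.unique(self.ids).size != n:
            raise ValueError("duplicate ids in pedigree")
        idx = np.arange(n)
        for par in (self.sire, self.dam):
            bad = (par >= idx) & (par >= 0)
            if np.any(bad):
                raise ValueError(
                    "pedigree not sorted parents-before-offspring "
                    "(or contains a cycle)"
                )

    def __len__(self) -> int:
        return self.ids.size

    @classmethod
    def from_parent_ids(cls, ids, sire_ids, dam_ids, birth_cycle=None
                        ) -> "PedigreeTable":
        """Build from parallel arrays of animal/sire/dam labels.

        Parent labels absent from ``ids`` (including -1/0 conventions for
        unknown) are treated as unknown founders.  Records must already be
        ordered parents before offspring.
        """
        ids = np.asarray(ids, dtype=np.int64)
        lookup = {int(v): i for i, v in enumerate(ids)}
        def to_pos(parents):
            return np.array([lookup.get(int(p), -1) for p in parents],
                            dtype=np.int64)
        bc = None if birth_cycle is None else np.asarray(birth_cycle)
        return cls(ids, to_pos(sire_ids), to_pos(dam_ids), bc)

    def positions_of(self, ids) -> np.ndarray:
        lookup = {int(v): i for i, v in enumerate(self.ids)}
        try:
            return np.array([lookup[int(i)] for i in np.asarray(ids)],
                            dtype=np.int64)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"id {e} not in pedigree") from None

    def ancestor_closure(self, positions: np.ndarray) -> np.ndarray:
        """Positions of the given animals plus all their ancestors."""
        mask = np.zeros(len(self), dtype=bool)
        mask[positions] = True
        _closure_scan(mask, self.sire, self.dam)
        return np.flatnonzero(mask)

    def restrict(self, positions: np.ndarray) -> "PedigreeTable":
        """Sub-pedigree containing exactly ``positions`` (must be
        closed under the parent relation or parents become unknown)."""
        positions = np.sort(np.asarray(positions, dtype=np.int64))
        new_pos = -np.ones(len(self), dtype=np.int64)
        new_pos[positions] = np.arange(positions.size)
        def remap(par):
            out = par[positions].copy()
            known = out >= 0
            out[known] = new_pos[out[known]]
            return out
        bc = None if self.birth_cycle is None else self.birth_cycle[positions]
        return PedigreeTable(self.ids[positions], remap(self.sire),
                             remap(self.dam), bc)


@njit(cache=True)
def _closure_scan(mask, sire, dam):
    for i in range(mask.size - 1, -1, -1):
        if mask[i]:
            if sire[i] >= 0:
                mask[sire[i]] = True
            if dam[i] >= 0:
                mask[dam[i]] = True


@njit(cache=True)
def _heap_push(heap, hsize, val):
    heap[hsize] = val
    k = hsize
    while k > 0:
        p = (k - 1) // 2
        if heap[k] > heap[p]:
            heap[k], heap[p] = heap[p], heap[k]
            k = p
        else:
            break
    return hsize + 1


@njit(cache=True)
def _heap_pop(heap, hsize):
    top = heap[0]
    hsize -= 1
    heap[0] = heap[hsize]
    k = 0
    while True:
        c = 2 * k + 1
        if c >= hsize:
            break
        if c + 1 < hsize and heap[c + 1] > heap[c]:
            c += 1
        if heap[c] > heap[k]:
            heap[k], heap[c] = heap[c], heap[k]
            k = c
        else:
            break
    return top, hsize


@njit(cache=True)
def _inbreeding_ml(sire, dam, F, start):
    """Meuwissen & Luo (1992) inbreeding, filling ``F[start:]`` in place.

    Ancestors are visited in decreasing position order via a max-heap so
    each ancestor's total contribution L is accumulated before use.
    """
    n = sire.size
    L = np.zeros(n)
    inheap = np.zeros(n, dtype=np.bool_)
    heap = np.empty(n, dtype=np.int64)
    for i in range(start, n):
        s = sire[i]
        d = dam[i]
        if s < 0 or d < 0:
            F[i] = 0.0
            continue
        hsize = 0
        L[i] = 1.0
        hsize = _heap_push(heap, hsize, i)
        inheap[i] = True
        acc = 0.0
        while hsize > 0:
            j, hsize = _heap_pop(heap, hsize)
            inheap[j] = False
            sj = sire[j]
            dj = dam[j]
            fs = F[sj] if sj >= 0 else -1.0
            fd = F[dj] if dj >= 0 else -1.0
            dj_var = 0.5 - 0.25 * (fs + fd)
            lj = L[j]
            acc += lj * lj * dj_var
            if sj >= 0:
                L[sj] += 0.5 * lj
                if not inheap[sj]:
                    hsize = _heap_push(heap, hsize, sj)
                    inheap[sj] = True
            if dj >= 0:
                L[dj] += 0.5 * lj
                if not inheap[dj]:
                    hsize = _heap_push(heap, hsize, dj)
                    inheap[dj] = True
            L[j] = 0.0
        F[i] = acc - 1.0
    return F


def inbreeding(pedigree: PedigreeTable, F: Optional[np.ndarray] = None,
               start: int = 0) -> np.ndarray:
    """Pedigree inbreeding coefficients.

    With ``F``/``start`` given, only entries from ``start`` on are
    (re)computed — used to maintain inbreeding incrementally as cohorts
    are born.
    """
    if F is None:
        F = np.zeros(len(pedigree))
        start = 0
    return _inbreeding_ml(pedigree.sire, pedigree.dam, F, start)


def mendelian_variances(pedigree: PedigreeTable,
                        F: Optional[np.ndarray] = None) -> np.ndarray:
    """Mendelian-sampling variance d_i given parental inbreeding."""
    if F is None:
        F = inbreeding(pedigree)
    fs = np.where(pedigree.sire >= 0, F[pedigree.sire], -1.0)
    fd = np.where(pedigree.dam >= 0, F[pedigree.dam], -1.0)
    return 0.5 - 0.25 * (fs + fd)


def build_A(pedigree: PedigreeTable) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method.

    Unknown parents are unrelated, non-inbred founders.  Quadratic in
    pedigree size; intended for moderate pedigrees and as the reference
    for the sparse routines.
    """
    n = len(pedigree)
    A = np.zeros((n, n))
    sire, dam = pedigree.sire, pedigree.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


def build_A_inverse(pedigree: PedigreeTable,
                    F: Optional[np.ndarray] = None) -> sp.csr_matrix:
    """Sparse inverse of A by Henderson's rules with inbreeding.

    Uses Mendelian-sampling variances from Meuwissen-Luo inbreeding, so
    the result is the exact inverse of :func:`build_A`.
    """
    n = len(pedigree)
    d = mendelian_variances(pedigree, F)
    alpha = 1.0 / d
    sire, dam = pedigree.sire, pedigree.dam
    rows, cols, vals = [], [], []
    idx = np.arange(n)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    add(idx, idx, alpha)
    for par in (sire, dam):
        has = par >= 0
        add(idx[has], par[has], -0.5 * alpha[has])
        add(par[has], idx[has], -0.5 * alpha[has])
    both = (sire >= 0) & (dam >= 0)
    s_only = (sire >= 0)
    d_only = (dam >= 0)
    add(sire[s_only], sire[s_only], 0.25 * alpha[s_only])
    add(dam[d_only], dam[d_only], 0.25 * alpha[d_only])
    add(sire[both], dam[both], 0.25 * alpha[both])
    add(dam[both], sire[both], 0.25 * alpha[both])
    rows = np.concatenate([np.atleast_1d(r) for r in rows])
    cols = np.concatenate([np.atleast_1d(c) for c in cols])
    vals = np.concatenate([np.atleast_1d(v) for v in vals])
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    return Ainv.tocsr()


def relationship_submatrix(pedigree: PedigreeTable, positions,
                           F: Optional[np.ndarray] = None) -> np.ndarray:
    """Dense block ``A[S, S]`` without forming the full A.

    Restricts the pedigree to the ancestor closure of S, then uses
    ``A = T D T'``: the needed rows of T come from a sparse triangular
    solve, giving ``A[S,S] = (T_S) D (T_S)'``.
    """
    positions = np.asarray(positions, dtype=np.int64)
    closure = pedigree.ancestor_closure(positions)
    sub = pedigree.restrict(closure)
    loc = np.searchsorted(closure, np.sort(positions))
    order = np.argsort(positions)
    n = len(sub)
    d = mendelian_variances(sub, None if F is None else F[closure])
    rows, cols, vals = [], [], []
    idx = np.arange(n)
    for par in (sub.sire, sub.dam):
        has = par >= 0
        rows.append(idx[has])
        cols.append(par[has])
        vals.append(np.full(has.sum(), -0.5))
    rows.append(idx)
    cols.append(idx)
    vals.append(np.ones(n))
    ImP = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n)).tocsc()
    # rows of T for S: solve (I-P)' Y = E_S
    E = np.zeros((n, positions.size))
    E[loc, np.arange(positions.size)] = 1.0
    lu = splu(ImP.T.tocsc(), permc_spec="NATURAL",
              options={"SymmetricMode": False})
    Y = lu.solve(E)  # n x k, column j = T' e_{s_j}
    from scipy.linalg.blas import dsyrk
    X = Y * np.sqrt(d)[:, None]
    Ablock_sorted = dsyrk(1.0, X, trans=1, lower=0)
    Ablock_sorted = Ablock_sorted + np.triu(Ablock_sorted, 1).T
    # undo the sorting applied to positions
    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)
    return Ablock_sorted[np.ix_(inv, inv)]


def cohort_relationship(pedigree: PedigreeTable, ids) -> np.ndarray:
    """``A[S, S]`` for a cohort given by animal labels."""
    return relationship_submatrix(pedigree, pedigree.positions_of(ids))
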