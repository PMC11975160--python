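"""Genetic evaluation: pedigree BLUP and single-step GBLUP.

Breeding values are estimated from the two-trait animal-model mixed-model
equations with trait means as the only fixed effects and known variance
components (the true simulation parameters).  The covariance structure of
the animal effect is either the pedigree numerator relationship matrix A
(PBLUP) or the single-step H matrix combining A with a VanRaden genomic
relationship matrix for the genotyped subset (ssGBLUP), entering the
equations through its sparse-plus-dense inverse

    H^-1 = A^-1 + [[0, 0], [0, Ghat^-1 - A22^-1]].

Systems without a genomic part are solved directly by sparse LU; the
ssGBLUP equations are solved by conjugate gradients preconditioned with
the factorized pedigree-only coefficient matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.sparse.linalg import LinearOperator, cg, splu

from .relationship import (PedigreeTable, build_A, build_A_inverse,
                           relationship_submatrix)
from .traits import TraitParams

__all__ = [
    "VarianceComponents", "EvaluationWindow", "EvaluationResult",
    "EvalConfig", "build_A", "build_A_inverse", "build_G", "blend_G",
    "HInverse", "build_H_inverse", "build_window", "solve_mme", "tmi",
    "ebv_accuracy", "evaluate",
]


class EvaluationError(RuntimeError):
    pass


@dataclass(frozen=True)
class VarianceComponents:
    """Known 2x2 genetic covariance and diagonal residual covariance."""

    G0: np.ndarray
    R0: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "G0", np.asarray(self.G0, dtype=float))
        object.__setattr__(self, "R0", np.asarray(self.R0, dtype=float))
        if self.G0.shape != self.R0.shape:
            raise ValueError("G0 and R0 must have matching shape")
        off = self.R0 - np.diag(np.diag(self.R0))
        if np.any(off != 0):
            raise ValueError("residual covariances must be diagonal")
        for M in (self.G0, self.R0):
            if np.any(np.linalg.eigvalsh(M) <= 0):
                raise ValueError("variance components must be positive definite")

    @classmethod
    def from_params(cls, params: TraitParams) -> "VarianceComponents":
        return cls(params.G0, params.R0)

    @property
    def n_traits(self) -> int:
        return self.G0.shape[0]


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation-window and solver settings."""

    window_cycles: int = 10       # data window: animals born in last N cycles
    pedigree_depth: int = 7       # extra ancestor cycles kept beyond window
    g_blend: float = 0.05         # weight of A22 blended into G
    cg_tol: float = 1e-8
    cg_maxiter: int = 5000


@dataclass
class EvaluationWindow:
    """Animals, pedigree subset and records entering one evaluation."""

    pedigree: PedigreeTable      # ids are global animal ids
    y: np.ndarray                # (n, 2), NaN where no record
    genotyped: np.ndarray        # bool mask over window animals
    F: Optional[np.ndarray] = None
    cycle: int = 0

    @property
    def ids(self) -> np.ndarray:
        return self.pedigree.ids

    @property
    def n(self) -> int:
        return len(self.pedigree)


@dataclass
class EvaluationResult:
    """EBVs for every animal of the window, both traits."""

    ids: np.ndarray
    ebv: np.ndarray              # (n, 2)
    fixed: np.ndarray            # (2,) trait means
    method: str
    n_iter: int = 0
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._index:
            self._index = {int(i): k for k, i in enumerate(self.ids)}

    @property
    def tmi(self) -> np.ndarray:
        return self.ebv.sum(axis=1)

    def contains(self, ids) -> np.ndarray:
        return np.array([int(i) in self._index for i in np.atleast_1d(ids)])

    def ebv_of(self, ids) -> np.ndarray:
        pos = [self._index[int(i)] for i in np.atleast_1d(ids)]
        return self.ebv[pos]

    def tmi_of(self, ids) -> np.ndarray:
        return self.ebv_of(ids).sum(axis=1)


def tmi(result: EvaluationResult) -> np.ndarray:
    """Total merit index: equal-weight sum of the two trait EBVs.

    Both traits are simulated with the same genetic variance, so the raw
    sum is the equal-weight index.
    """
    return result.tmi


def ebv_accuracy(result: EvaluationResult, cohort_ids, tbv: np.ndarray
                 ) -> np.ndarray:
    """Pearson correlation of TBV and EBV within a cohort, per trait.

    ``tbv`` has one row per cohort id.  Animals without an EBV (outside
    the evaluated window) are skipped; with fewer than three usable
    animals or zero EBV variance the accuracy is reported missing (NaN).
    """
    cohort_ids = np.atleast_1d(np.asarray(cohort_ids))
    have = result.contains(cohort_ids)
    tbv = np.atleast_2d(tbv)[have]
    if have.sum() < 3:
        return np.full(2, np.nan)
    ebv = result.ebv_of(cohort_ids[have])
    out = np.empty(2)
    for t in range(2):
        se, st = ebv[:, t].std(), tbv[:, t].std()
        out[t] = np.nan if se == 0 or st == 0 else float(
            np.corrcoef(tbv[:, t], ebv[:, t])[0, 1])
    return out


# ----------------------------------------------------------------------
# Genomic relationship matrices
# ----------------------------------------------------------------------

def build_G(dosage: np.ndarray, freqs: Optional[np.ndarray] = None
            ) -> np.ndarray:
    """VanRaden (method 1) genomic relationship matrix.

    ``dosage`` is the (k, m) allele-count matrix of the genotyped
    animals; centering frequencies default to those observed in this set.
    """
    dosage = np.asarray(dosage, dtype=np.float64)
    if dosage.shape[0] < 2:
        raise EvaluationError("need at least two genotyped individuals")
    p = dosage.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs)
    het = 2.0 * np.sum(p * (1.0 - p))
    if het <= 0:
        raise EvaluationError("all markers monomorphic in genotyped set")
    Z = dosage - 2.0 * p[None, :]
    from scipy.linalg.blas import dsyrk
    G = dsyrk(1.0 / het, Z, trans=0, lower=0)
    return G + np.triu(G, 1).T


def blend_G(G: np.ndarray, A22: np.ndarray, weight: float = 0.05
            ) -> np.ndarray:
    """``Ghat = (1 - w) G + w A22`` — guarantees invertibility."""
    return (1.0 - weight) * G + weight * A22


@dataclass
class HInverse:
    """Sparse-plus-dense representation of the ssGBLUP H inverse.

    The genomic correction ``Ghat^-1 - A22^-1`` is held as the two
    Cholesky factorizations and applied through triangular solves; the
    explicit dense block is only materialized on demand (small systems,
    testing).
    """

    A_inv: sp.spmatrix
    genotyped_pos: np.ndarray         # positions of genotyped animals
    _chol_G: Optional[tuple] = None
    _chol_A22: Optional[tuple] = None
    _delta: Optional[np.ndarray] = None

    @property
    def shape(self):
        return self.A_inv.shape

    @property
    def has_genomic(self) -> bool:
        return self._chol_G is not None

    def apply_delta(self, V: np.ndarray) -> np.ndarray:
        """``(Ghat^-1 - A22^-1) @ V`` for a (k, ...) block."""
        return cho_solve(self._chol_G, V) - cho_solve(self._chol_A22, V)

    @property
    def delta(self) -> Optional[np.ndarray]:
        if not self.has_genomic:
            return None
        if self._delta is None:
            k = self.genotyped_pos.size
            self._delta = self.apply_delta(np.eye(k))
        return self._delta

    def matvec(self, v: np.ndarray) -> np.ndarray:
        out = self.A_inv @ v
        if self.has_genomic:
            g = self.genotyped_pos
            out[g] += self.apply_delta(v[g])
        return out

    def toarray(self) -> np.ndarray:
        out = np.asarray(self.A_inv.todense())
        if self.has_genomic:
            g = self.genotyped_pos
            out[np.ix_(g, g)] += self.delta
        return out


def build_H_inverse(A_inv: sp.spmatrix, A22: np.ndarray,
                    G_blended: np.ndarray, genotyped_pos) -> HInverse:
    """Assemble H^-1 from the pedigree inverse and the genomic block."""
    genotyped_pos = np.asarray(genotyped_pos, dtype=np.int64)
    if genotyped_pos.size == 0:
        return HInverse(A_inv.tocsr(), genotyped_pos)
    try:
        cG = cho_factor(G_blended)
    except np.linalg.LinAlgError as e:
        raise EvaluationError(
            f"blended G is singular ({e}); check blending weight") from e
    cA = cho_factor(A22)
    return HInverse(A_inv.tocsr(), genotyped_pos, cG, cA)


# ----------------------------------------------------------------------
# Window construction
# ----------------------------------------------------------------------

def build_window(population, cycle: int, candidate_ids: Sequence,
                 reference_ids: Sequence,
                 config: EvalConfig = EvalConfig()) -> EvaluationWindow:
    """Collect the animals and records entering one evaluation.

    Data animals are those born in the last ``window_cycles`` breeding
    cycles that still matter (selection candidates, living animals and
    phenotyped animals), plus the genomic reference population, which is
    retained regardless of age (the reference has no sliding base).  The
    pedigree is extended ``pedigree_depth`` cycles further back; older
    ancestors are truncated to unknown-parent founders.
    """
    candidate_ids = np.asarray(candidate_ids, dtype=np.int64)
    reference_ids = np.asarray(reference_ids, dtype=np.int64)
    born = population.birth_cycle
    in_window = born > cycle - config.window_cycles
    relevant = in_window & (population.alive | population.phenotyped)
    core = np.unique(np.concatenate(
        [np.flatnonzero(relevant), candidate_ids, reference_ids]))

    ped = population.pedigree_table()
    closure = ped.ancestor_closure(core)
    cutoff = cycle - (config.window_cycles - 1) - config.pedigree_depth
    in_core = np.zeros(population.n, dtype=bool)
    in_core[core] = True
    keep = closure[(born[closure] >= cutoff) | in_core[closure]]
    sub = ped.restrict(keep)

    ids = sub.ids
    is_ref = np.zeros(population.n, dtype=bool)
    is_ref[reference_ids] = True
    usable = in_window[ids] | is_ref[ids]
    y = np.where(usable[:, None], population.phen[ids], np.nan)
    genotyped = population.genotyped[ids]
    return EvaluationWindow(sub, y, genotyped, F=population.F[ids],
                            cycle=cycle)


# ----------------------------------------------------------------------
# Mixed-model equations
# ----------------------------------------------------------------------

def _assemble_sparse(window: EvaluationWindow, K_inv: sp.spmatrix,
                     vc: VarianceComponents):
    """Sparse MME coefficient matrix and RHS, unknowns [b; u1; u2]."""
    n = window.n
    T = vc.n_traits
    rinv = 1.0 / np.diag(vc.R0)
    G0inv = np.linalg.inv(vc.G0)
    ph = ~np.isnan(window.y)
    if not np.all(ph.any(axis=0)):
        raise EvaluationError("a trait has no phenotype records in window")

    blocks_xx = sp.diags([ph[:, t].sum() * rinv[t] for t in range(T)])
    xz_rows = []
    for t in range(T):
        row = np.zeros(T * n)
        row[t * n:(t + 1) * n][ph[:, t]] = rinv[t]
        xz_rows.append(row)
    Bxz = sp.csr_matrix(np.vstack(xz_rows))
    data_diag = np.concatenate(
        [np.where(ph[:, t], rinv[t], 0.0) for t in range(T)])
    C = sp.bmat([
        [blocks_xx, Bxz],
        [Bxz.T, sp.diags(data_diag) + sp.kron(G0inv, K_inv)],
    ], format="csc")

    y0 = np.nan_to_num(window.y)
    rhs = np.concatenate([
        [rinv[t] * y0[:, t].sum() for t in range(T)],
        np.concatenate([rinv[t] * np.where(ph[:, t], y0[:, t], 0.0)
                        for t in range(T)]),
    ])
    return C, rhs


def solve_mme(window: EvaluationWindow, relationship_inverse,
              vc: VarianceComponents, method: str = "PBLUP",
              config: EvalConfig = EvalConfig()) -> EvaluationResult:
    """Solve the two-trait mixed-model equations.

    ``relationship_inverse`` is a sparse matrix (PBLUP) or an
    :class:`HInverse` (ssGBLUP).  Unphenotyped animals obtain EBVs through
    relationships.  Purely sparse systems are solved exactly by sparse LU;
    with a dense genomic correction, preconditioned CG is used and
    required to reach a relative residual below ``config.cg_tol``.
    """
    n = window.n
    T = vc.n_traits
    hinv = None
    if isinstance(relationship_inverse, HInverse):
        K_sparse = relationship_inverse.A_inv
        if relationship_inverse.has_genomic:
            hinv = relationship_inverse
        gpos = relationship_inverse.genotyped_pos
    else:
        K_sparse = sp.csr_matrix(relationship_inverse)
        gpos = None

    Csp, rhs = _assemble_sparse(window, K_sparse, vc)
    lu = splu(Csp)
    n_iter = 0
    if hinv is None:
        sol = lu.solve(rhs)
    else:
        G0inv = np.linalg.inv(vc.G0)
        off = T  # fixed-effect equations come first

        def matvec(v):
            out = Csp @ v
            u = v[off:].reshape(T, n)
            corr = G0inv @ hinv.apply_delta(u[:, gpos].T).T
            for t in range(T):
                out[off + t * n:off + (t + 1) * n][gpos] += corr[t]
            return out

        op = LinearOperator(Csp.shape, matvec=matvec)
        M = LinearOperator(Csp.shape, matvec=lu.solve)
        sol, info = cg(op, rhs, rtol=config.cg_tol, atol=0.0,
                       maxiter=config.cg_maxiter, M=M)
        resid = np.linalg.norm(matvec(sol) - rhs) / np.linalg.norm(rhs)
        if info != 0 or not np.isfinite(resid) or resid > 100 * config.cg_tol:
            raise EvaluationError(
                f"MME solver did not converge (info={info}, "
                f"relative residual={resid:.2e})")
        n_iter = int(info) if info > 0 else -1
    b = sol[:T]
    u = sol[T:].reshape(T, n).T
    return EvaluationResult(window.ids.copy(), u, b, method, n_iter)


def evaluate(population, cycle: int, candidate_ids, reference_ids,
             vc: VarianceComponents, method: str = "PBLUP",
             config: EvalConfig = EvalConfig()) -> EvaluationResult:
    """One full genetic evaluation of the current population state."""
    window = build_window(population, cycle, candidate_ids, reference_ids,
                          config)
    A_inv = build_A_inverse(window.pedigree, F=window.F)
    gpos = np.flatnonzero(window.genotyped)
    if method == "ssGBLUP" and gpos.size >= 2:
        dosage = population.genotype_dosage(window.ids[gpos])
        G = build_G(dosage)
        A22 = relationship_submatrix(window.pedigree, gpos, F=window.F)
        Ghat = blend_G(G, A22, config.g_blend)
        K = build_H_inverse(A_inv, A22, Ghat, gpos)
    elif method in ("ssGBLUP", "PBLUP"):
        K = A_inv
    else:
        raise ValueError(f"unknown evaluation method {method!r}")
    return solve_mme(window, K, vc, method, config)
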