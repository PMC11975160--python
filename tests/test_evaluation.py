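"""Mixed-model equations against closed-form and GLS oracles."""

import numpy as np
import pytest

from merinosim.evaluation import (EvalConfig, EvaluationWindow,
                                  EvaluationError, VarianceComponents,
                                  blend_G, build_A, build_A_inverse, build_G,
                                  build_H_inverse, ebv_accuracy, solve_mme)
from merinosim.relationship import PedigreeTable
from tests.conftest import random_pedigree


def make_window(ped, y, genotyped=None):
    geno = np.zeros(len(ped), bool) if genotyped is None else genotyped
    return EvaluationWindow(ped, np.asarray(y, float), geno)


def gls_blup_oracle(A_like, y, vc):
    """Multi-trait BLUP by dense GLS: u = (K (x) G0) Z' V^-1 (y - X b).

    Independent of the MME path; handles missing records by dropping the
    corresponding rows of Z.  ``A_like`` is the dense relationship (A or
    H) of all animals.
    """
    n, T = y.shape
    K = np.asarray(A_like)
    G0, R0 = vc.G0, vc.R0
    recs = [(i, t) for t in range(T) for i in range(n)
            if np.isfinite(y[i, t])]
    nr = len(recs)
    Z = np.zeros((nr, T * n))
    X = np.zeros((nr, T))
    R = np.zeros((nr, nr))
    yv = np.zeros(nr)
    for r, (i, t) in enumerate(recs):
        Z[r, t * n + i] = 1.0
        X[r, t] = 1.0
        R[r, r] = R0[t, t]
        yv[r] = y[i, t]
    Gbig = np.kron(G0, K)
    V = Z @ Gbig @ Z.T + R
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ yv)
    u = Gbig @ Z.T @ Vi @ (yv - X @ b)
    return b, u.reshape(T, n).T


@pytest.fixture
def vc():
    from merinosim.traits import TraitParams
    return VarianceComponents.from_params(TraitParams())


class TestVarianceComponents:
    def test_rejects_residual_covariance(self):
        with pytest.raises(ValueError):
            VarianceComponents(np.eye(2), np.array([[1.0, 0.5], [0.5, 1.0]]))


class TestSolveMME:
    def test_single_animal_closed_form(self, vc):
        # one animal, K = I: u = (Z'R^-1 Z + G0^-1)^-1 Z'R^-1 (y - b)
        ped = PedigreeTable(np.array([0]), np.array([-1]), np.array([-1]))
        y = np.array([[105.0, 95.0]])
        res = solve_mme(make_window(ped, y), np.eye(1), vc)
        dev = y[0] - res.fixed
        lhs = np.diag(1 / np.diag(vc.R0)) + np.linalg.inv(vc.G0)
        expected = np.linalg.solve(lhs, dev / np.diag(vc.R0))
        np.testing.assert_allclose(res.ebv[0], expected, atol=1e-8)

    def test_no_phenotypes_raises(self, vc):
        ped = PedigreeTable(np.arange(2), -np.ones(2, int), -np.ones(2, int))
        with pytest.raises(EvaluationError):
            solve_mme(make_window(ped, np.full((2, 2), np.nan)),
                      np.eye(2), vc)

    @pytest.mark.parametrize("seed,n", [(0, 30), (1, 50)])
    def test_matches_gls_oracle_pedigree(self, vc, seed, n):
        rng = np.random.default_rng(seed)
        sire, dam = random_pedigree(n, rng)
        ped = PedigreeTable(np.arange(n), sire, dam)
        y = 100 + rng.standard_normal((n, 2)) * 5
        y[rng.random(n) < 0.4] = np.nan  # unphenotyped animals
        if not np.isfinite(y).any(axis=0).all():
            y[0] = [100.0, 100.0]
        A = build_A(ped)
        res = solve_mme(make_window(ped, y), build_A_inverse(ped), vc)
        b, u = gls_blup_oracle(A, y, vc)
        np.testing.assert_allclose(res.fixed, b, atol=1e-6)
        np.testing.assert_allclose(res.ebv, u, atol=1e-6)

    def test_unphenotyped_get_parent_average(self, vc):
        # offspring of two evaluated parents, no own record: EBV is the
        # parent average (no other information flows in)
        ped = PedigreeTable(np.arange(3), np.array([-1, -1, 0]),
                            np.array([-1, -1, 1]))
        y = np.array([[110.0, 90.0], [104.0, 98.0], [np.nan, np.nan]])
        res = solve_mme(make_window(ped, y), build_A_inverse(ped), vc)
        np.testing.assert_allclose(res.ebv[2],
                                   0.5 * (res.ebv[0] + res.ebv[1]),
                                   atol=1e-8)


class TestG:
    def test_duplicate_genotype_off_diagonal(self):
        dosage = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 1]])
        G = build_G(dosage)
        assert G[0, 1] == pytest.approx(G[0, 0])

    def test_monomorphic_rejected(self):
        with pytest.raises(EvaluationError):
            build_G(np.array([[2, 0], [2, 0]]))

    def test_mean_diagonal_near_one_in_base(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, size=4000)
        dosage = rng.binomial(2, p, size=(300, 4000))
        G = build_G(dosage)
        assert np.mean(np.diag(G)) == pytest.approx(1.0, abs=0.05)

    def test_full_blend_returns_A22(self):
        A22 = np.array([[1.0, 0.25], [0.25, 1.0]])
        G = np.array([[1.1, 0.4], [0.4, 0.9]])
        np.testing.assert_allclose(blend_G(G, A22, weight=1.0), A22)


class TestHInverse:
    def test_no_genotypes_reduces_to_A_inverse(self):
        ped = PedigreeTable(np.arange(3), np.array([-1, -1, 0]),
                            np.array([-1, -1, 1]))
        Ainv = build_A_inverse(ped)
        H = build_H_inverse(Ainv, np.empty((0, 0)), np.empty((0, 0)),
                            np.array([], dtype=int))
        np.testing.assert_allclose(H.toarray(), Ainv.toarray())

    def test_G_equal_A22_consistency(self):
        rng = np.random.default_rng(2)
        sire, dam = random_pedigree(30, rng)
        ped = PedigreeTable(np.arange(30), sire, dam)
        A = build_A(ped)
        gpos = np.arange(20, 30)
        A22 = A[np.ix_(gpos, gpos)]
        H = build_H_inverse(build_A_inverse(ped), A22, A22.copy(), gpos)
        np.testing.assert_allclose(H.toarray(),
                                   build_A_inverse(ped).toarray(), atol=1e-8)

    def test_ssgblup_matches_dense_H_oracle(self, vc):
        # 20 animals, 5 genotyped: EBVs from the H^-1 MME must equal the
        # GLS oracle run on the dense H built by the join formula
        rng = np.random.default_rng(7)
        n = 20
        sire, dam = random_pedigree(n, rng)
        ped = PedigreeTable(np.arange(n), sire, dam)
        A = build_A(ped)
        gpos = np.arange(n - 5, n)
        A22 = A[np.ix_(gpos, gpos)]
        dosage = rng.binomial(2, rng.uniform(0.2, 0.8, 200), size=(5, 200))
        Ghat = blend_G(build_G(dosage), A22, 0.05)
        Hinv = build_H_inverse(build_A_inverse(ped), A22, Ghat, gpos)

        # dense H: H22 = Ghat, H12 = A12 A22^-1 Ghat, H11 adjusted
        rest = np.arange(n - 5)
        A11 = A[np.ix_(rest, rest)]
        A12 = A[np.ix_(rest, gpos)]
        A22i = np.linalg.inv(A22)
        H = np.zeros((n, n))
        H[np.ix_(gpos, gpos)] = Ghat
        H[np.ix_(rest, gpos)] = A12 @ A22i @ Ghat
        H[np.ix_(gpos, rest)] = H[np.ix_(rest, gpos)].T
        H[np.ix_(rest, rest)] = A11 + A12 @ A22i @ (Ghat - A22) @ A22i @ A12.T
        np.testing.assert_allclose(Hinv.toarray(), np.linalg.inv(H),
                                   atol=1e-8)

        y = 100 + rng.standard_normal((n, 2)) * 4
        y[:4] = np.nan
        res = solve_mme(make_window(ped, y), Hinv, vc, method="ssGBLUP")
        b, u = gls_blup_oracle(H, y, vc)
        np.testing.assert_allclose(res.ebv, u, atol=1e-6)
        np.testing.assert_allclose(res.fixed, b, atol=1e-6)


class TestAccuracy:
    def _result(self, ebv):
        from merinosim.evaluation import EvaluationResult
        ids = np.arange(len(ebv))
        return EvaluationResult(ids, np.asarray(ebv, float), np.zeros(2),
                                "PBLUP")

    def test_perfect_and_null_accuracy(self):
        rng = np.random.default_rng(0)
        tbv = rng.standard_normal((500, 2))
        res = self._result(tbv)
        np.testing.assert_allclose(
            ebv_accuracy(res, np.arange(500), tbv), [1.0, 1.0])
        res_rand = self._result(rng.standard_normal((500, 2)))
        acc = ebv_accuracy(res_rand, np.arange(500), tbv)
        assert np.all(np.abs(acc) < 0.15)

    def test_zero_variance_reported_missing(self):
        tbv = np.random.default_rng(1).standard_normal((10, 2))
        res = self._result(np.zeros((10, 2)))
        assert np.all(np.isnan(ebv_accuracy(res, np.arange(10), tbv)))

    def test_tmi_equal_weights(self):
        res = self._result([[1.0, 2.0], [0.0, 0.0]])
        np.testing.assert_allclose(res.tmi, [3.0, 0.0])
        # ranking invariant under adding a constant to one trait's EBVs
        shifted = self._result(np.array([[1.0, 7.0], [0.0, 5.0]]))
        assert np.argsort(shifted.tmi)[::-1].tolist() == \
            np.argsort(res.tmi)[::-1].tolist()
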