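"""Cost accounting, penalty maps and their invariants."""

import math
from fractions import Fraction

import numpy as np
import pytest

from lssurface.model import (
    AlleleMatrix,
    CopyPath,
    GenotypeSequence,
    Haplotype,
    PenaltySpec,
    alpha,
    alpha_from_p,
    beta,
    beta_from_p,
    diploid_mismatch_count,
    diploid_site_mismatch,
    equivalence_curve,
    mismatch_count,
    path_cost,
    penalty_ratio,
    switch_count,
)


@pytest.mark.parametrize(
    "path,expected",
    [
        ([2, 2, 2, 2], 0),
        ([0, 1, 0], 2),
        ([0, 0, 1, 1, 2], 2),
        ([5], 0),
    ],
)
def test_switch_count(path, expected):
    assert switch_count(CopyPath(np.array(path))) == expected


def test_empty_path_rejected():
    with pytest.raises(ValueError, match="empty"):
        CopyPath(np.array([], dtype=int))


def test_mismatch_count_examples(rng):
    H = AlleleMatrix(rng.integers(0, 2, size=(6, 3)))
    # constant path on a column that equals the focal: zero mismatches
    h = Haplotype(H.alleles[:, 1].copy())
    assert mismatch_count([1] * 6, h, H) == 0
    # one differing site
    H2 = AlleleMatrix(np.array([[0, 1], [0, 1]]))
    assert mismatch_count([0, 0], Haplotype(np.array([0, 1])), H2) == 1
    # random instance equals the per-site indicator sum
    path = rng.integers(0, 3, size=6)
    h2 = Haplotype(rng.integers(0, 2, size=6))
    expected = sum(int(h2.alleles[k] != H.alleles[k, path[k]]) for k in range(6))
    assert mismatch_count(path, h2, H) == expected


def test_mismatch_count_bad_index():
    H = AlleleMatrix(np.zeros((3, 2), dtype=int))
    with pytest.raises(ValueError, match="template panel"):
        mismatch_count([0, 5, 0], Haplotype(np.zeros(3, dtype=int)), H)


class TestDiploidMismatch:
    def test_exact_pair_reproduction_is_zero(self, rng):
        H = AlleleMatrix(rng.integers(0, 2, size=(5, 4)))
        g = GenotypeSequence(np.stack([H.alleles[:, 1], H.alleles[:, 3]], axis=1))
        assert diploid_mismatch_count([1] * 5, [3] * 5, g, H) == 0

    @pytest.mark.parametrize(
        "g_pair,t_pair,expected",
        [
            ((0, 0), (0, 1), 1),  # |{0} sym-diff {0,1}| = 1
            ((0, 1), (1, 1), 1),
            ((0, 0), (1, 1), 2),
            ((0, 1), (0, 1), 0),
        ],
    )
    def test_site_set_semantics(self, g_pair, t_pair, expected):
        H = AlleleMatrix(np.array([list(t_pair)]))
        g = GenotypeSequence(np.array([list(g_pair)]))
        assert diploid_site_mismatch(0, 0, 1, g, H) == expected

    def test_all_nine_biallelic_cases_equal_dosage_difference(self):
        # For biallelic data the set symmetric difference equals the
        # absolute dosage difference; enumerate every site configuration.
        for g_pair in [(0, 0), (0, 1), (1, 1)]:
            for t_pair in [(0, 0), (0, 1), (1, 1)]:
                H = AlleleMatrix(np.array([list(t_pair)]))
                g = GenotypeSequence(np.array([list(g_pair)]))
                got = diploid_site_mismatch(0, 0, 1, g, H)
                assert got == abs(sum(g_pair) - sum(t_pair))

    def test_symmetries(self, rng):
        L, N = 6, 4
        H = AlleleMatrix(rng.integers(0, 2, size=(L, N)))
        g_arr = rng.integers(0, 2, size=(L, 2))
        g = GenotypeSequence(g_arr)
        g_swapped = GenotypeSequence(g_arr[:, ::-1])
        p1 = rng.integers(0, N, size=L)
        p2 = rng.integers(0, N, size=L)
        base = diploid_mismatch_count(p1, p2, g, H)
        assert diploid_mismatch_count(p2, p1, g, H) == base
        assert diploid_mismatch_count(p1, p2, g_swapped, H) == base

    def test_length_mismatch_rejected(self):
        H = AlleleMatrix(np.zeros((3, 2), dtype=int))
        g = GenotypeSequence(np.zeros((3, 2), dtype=int))
        with pytest.raises(ValueError, match="lengths differ"):
            diploid_mismatch_count([0, 0], [0, 0, 0], g, H)


class TestPenaltyMaps:
    def test_boundaries_rejected(self):
        with pytest.raises(ValueError, match="1/4"):
            alpha_from_p(0.25)  # alpha would be 0
        with pytest.raises(ValueError, match="1/"):
            beta_from_p(1.0 / 101, 100)  # beta would be 0
        with pytest.raises(ValueError):
            PenaltySpec(N=100, p_theta=0.3, p_rho=1e-4)
        with pytest.raises(ValueError):
            PenaltySpec(N=100, p_theta=1e-3, p_rho=0.5)

    def test_positive_and_decreasing(self):
        N = 1000
        thetas = np.logspace(-6, 1, 25)
        vals = [alpha(t, N) for t in thetas]
        assert all(v > 0 for v in vals)
        assert all(a > b for a, b in zip(vals, vals[1:]))
        rhos = np.logspace(-6, 1, 25)
        bvals = [beta(r, N) for r in rhos]
        assert all(v > 0 for v in bvals)
        assert all(a > b for a, b in zip(bvals, bvals[1:]))
        # direct evaluation at the scaled recombination rate is finite
        assert 0 < beta(1e-4, 1000) < 100

    def test_penalty_ratio_monotone_in_theta(self):
        N = 200
        rho = 1e-3
        cs = [penalty_ratio(t, rho, N) for t in (1e-4, 1e-3, 1e-2, 1e-1)]
        assert all(a < b for a, b in zip(cs, cs[1:]))

    def test_original_parameterization_differs(self):
        assert alpha(1.0, 100, "original") != alpha(1.0, 100, "coalescent")
        with pytest.raises(ValueError, match="parameterization"):
            alpha(1.0, 100, "nope")

    def test_equivalence_curve_roundtrip(self):
        N = 500
        c = penalty_ratio(2e-3, 7e-4, N)
        grid = [0.01, 0.05, 0.1, 0.2, 0.24]
        for pt, pr in equivalence_curve(c, grid, N):
            assert 0 < pr < 1.0 / N
            assert beta_from_p(pr, N) / alpha_from_p(pt) == pytest.approx(c, rel=1e-10)

    def test_equivalence_curve_large_c_limit(self):
        # c -> infinity at fixed p_theta < 1/4 drives p_rho to 0
        (_, pr_big), = equivalence_curve(200.0, [0.1], 50)
        (_, pr_small), = equivalence_curve(1.0, [0.1], 50)
        assert pr_big < 1e-10 < pr_small

    def test_equivalence_curve_validates(self):
        with pytest.raises(ValueError, match="outside"):
            equivalence_curve(1.0, [0.3], 10)
        with pytest.raises(ValueError, match="positive"):
            equivalence_curve(-1.0, [0.1], 10)


class TestPathCost:
    def test_arithmetic(self, rng):
        H = AlleleMatrix(np.array([[0, 1], [0, 1], [1, 0]]))
        h = Haplotype(np.array([0, 0, 1]))
        assert path_cost([0, 0, 0], h, H, c=1.0) == 0.0
        # m=1, r=2, c=0.5 -> 2.0
        h2 = Haplotype(np.array([0, 1, 0]))
        pth = [0, 1, 0]
        assert mismatch_count(pth, h2, H) == 1 and switch_count(pth) == 2
        assert path_cost(pth, h2, H, c=0.5) == pytest.approx(2.0)
        with pytest.raises(ValueError, match="positive"):
            path_cost(pth, h2, H, c=0.0)

    def test_unnormalized_cost_is_scaled_normalized_cost(self, rng):
        # alpha*m + beta*k == alpha * (m + c*k): ranking by the normalized
        # cost is the ranking by the full negative log-likelihood.
        N, L = 3, 5
        H = AlleleMatrix(rng.integers(0, 2, size=(L, N)))
        h = Haplotype(rng.integers(0, 2, size=L))
        theta, rho = 3e-3, 1e-3
        a, b = alpha(theta, N), beta(rho, N)
        c = b / a
        for _ in range(20):
            pth = rng.integers(0, N, size=L)
            m, k = mismatch_count(pth, h, H), switch_count(pth)
            assert a * m + b * k == pytest.approx(a * path_cost(pth, h, H, c))

    def test_bounds_invariant(self, rng):
        for _ in range(50):
            L = int(rng.integers(1, 9))
            pth = rng.integers(0, 5, size=L)
            assert 0 <= switch_count(pth) <= L - 1


def test_genotypes_stored_unordered():
    g = GenotypeSequence(np.array([[1, 0], [0, 1]]))
    assert (g.pairs == np.array([[0, 1], [0, 1]])).all()


def test_panel_validation():
    with pytest.raises(ValueError, match="alphabet"):
        AlleleMatrix(np.array([[0, 2]]))
    with pytest.raises(ValueError, match="increasing"):
        AlleleMatrix(np.array([[0], [1]]), positions=np.array([5.0, 5.0]))
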