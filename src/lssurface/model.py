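"""Core data types and cost accounting for the Li-Stephens copying model.

The Li-Stephens (LS) model treats a "focal" chromosome of ``L`` linked
markers as a mosaic of ``N`` template chromosomes.  A *copying path*
``pi`` assigns a template to every site; its quality is summarized by two
integers: ``k(pi)``, the number of template switches (crossover
recombinations), and ``m(pi)``, the number of allele mismatches between
the focal sequence and the templates it copies from.  Up to an additive
constant the negative log-likelihood of a path is::

    alpha(theta) * m(pi) + beta(rho) * k(pi)

where ``alpha`` and ``beta`` are decreasing functions of the mutation and
recombination rates.  Because only the ratio ``c = beta/alpha`` affects
which path is optimal, the whole ``(theta, rho)`` plane collapses onto a
one-parameter family: everything downstream of this module works with a
single switch penalty ``beta`` after normalizing ``alpha = 1``.

This module defines the containers (panel, haplotype, genotype sequence,
path), the exact integer counters ``k`` and ``m``, and the maps between
rate parameters and penalties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BIALLELIC",
    "NUCLEOTIDES",
    "AlleleMatrix",
    "Haplotype",
    "GenotypeSequence",
    "CopyPath",
    "PenaltySpec",
    "switch_count",
    "mismatch_count",
    "diploid_mismatch_count",
    "diploid_site_mismatch",
    "p_theta_coalescent",
    "p_theta_original",
    "p_rho_coalescent",
    "alpha",
    "beta",
    "alpha_from_p",
    "beta_from_p",
    "penalty_ratio",
    "equivalence_curve",
    "path_cost",
]

#: Default allele alphabet: a binary genotype matrix (0 = ancestral, 1 = derived).
BIALLELIC: tuple[int, ...] = (0, 1)

#: Four-letter nucleotide alphabet, encoded 0..3 internally.
NUCLEOTIDES: tuple[str, ...] = ("a", "c", "g", "t")


def _as_int_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.size and not np.issubdtype(arr.dtype, np.integer):
        raise TypeError(f"{name} must contain integer allele codes, got {arr.dtype}")
    return arr.astype(np.int64, copy=False)


@dataclass(frozen=True)
class AlleleMatrix:
    """Template panel ``H``: an ``L x N`` matrix of allele codes.

    Rows are sites, columns are template haplotypes.  ``positions``, if
    given, are strictly increasing physical coordinates (bp) of the sites.
    """

    alleles: np.ndarray
    alphabet: tuple = BIALLELIC
    positions: np.ndarray | None = None

    def __post_init__(self):
        arr = _as_int_array(self.alleles, "alleles")
        if arr.ndim != 2:
            raise ValueError("panel must be a 2-D (sites x templates) matrix")
        L, N = arr.shape
        if L < 1 or N < 1:
            raise ValueError("panel must have at least one site and one template")
        if arr.size and (arr.min() < 0 or arr.max() >= len(self.alphabet)):
            raise ValueError("allele code outside the declared alphabet")
        object.__setattr__(self, "alleles", arr)
        if self.positions is not None:
            pos = np.asarray(self.positions, dtype=float)
            if pos.shape != (L,):
                raise ValueError("positions must have one entry per site")
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing")
            object.__setattr__(self, "positions", pos)

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_templates(self) -> int:
        return self.alleles.shape[1]


@dataclass(frozen=True)
class Haplotype:
    """A focal haplotype: a length-``L`` vector of allele codes."""

    alleles: np.ndarray

    def __post_init__(self):
        arr = _as_int_array(self.alleles, "alleles")
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("haplotype must be a nonempty 1-D vector")
        object.__setattr__(self, "alleles", arr)

    def __len__(self) -> int:
        return self.alleles.size


@dataclass(frozen=True)
class GenotypeSequence:
    """A diplotype: a length-``L`` sequence of *unordered* allele pairs.

    Pairs are stored canonically sorted so that ``{0,1}`` and ``{1,0}``
    compare equal, matching the unphased-genotype semantics.
    """

    pairs: np.ndarray

    def __post_init__(self):
        arr = _as_int_array(self.pairs, "pairs")
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
            raise ValueError("genotypes must be a nonempty L x 2 array")
        object.__setattr__(self, "pairs", np.sort(arr, axis=1))

    def __len__(self) -> int:
        return self.pairs.shape[0]

    @classmethod
    def from_haplotypes(cls, h1: Haplotype, h2: Haplotype) -> "GenotypeSequence":
        if len(h1) != len(h2):
            raise ValueError("haplotype lengths differ")
        return cls(np.stack([h1.alleles, h2.alleles], axis=1))


@dataclass(frozen=True)
class CopyPath:
    """A copying path: template indices (0-based) at each site."""

    states: np.ndarray

    def __post_init__(self):
        arr = _as_int_array(self.states, "states")
        if arr.ndim != 1:
            raise ValueError("path must be 1-D")
        if arr.size == 0:
            raise ValueError("empty path")
        object.__setattr__(self, "states", arr)

    def __len__(self) -> int:
        return self.states.size


def _states(path) -> np.ndarray:
    if isinstance(path, CopyPath):
        return path.states
    return CopyPath(np.asarray(path)).states


def switch_count(path) -> int:
    """Number of template switches ``k(pi)`` along a path.

    Counts adjacent positions with different templates; a length-1 path
    has no switches.
    """
    s = _states(path)
    return int(np.count_nonzero(s[1:] != s[:-1]))


def mismatch_count(path, h: Haplotype, H: AlleleMatrix) -> int:
    """Number of mismatches ``m(pi)`` between the focal prefix and the panel.

    The path may be shorter than the panel; only its prefix is scored.
    """
    s = _states(path)
    hv = h.alleles if isinstance(h, Haplotype) else _as_int_array(h, "h")
    if s.size > H.n_sites or s.size > hv.size:
        raise ValueError("path longer than the panel / focal haplotype")
    if s.min() < 0 or s.max() >= H.n_templates:
        raise ValueError("path index outside the template panel")
    idx = np.arange(s.size)
    return int(np.count_nonzero(hv[: s.size] != H.alleles[idx, s]))


def diploid_site_mismatch(site: int, n1: int, n2: int, g: GenotypeSequence, H: AlleleMatrix) -> int:
    """Per-site diploid mismatch: |{g1,g2} symmetric-difference {H[l,n1],H[l,n2]}|.

    Set (not multiset) semantics, exactly as the likelihood prescribes;
    symmetric in (n1, n2).  Values are 0, 1 or 2.
    """
    if not (0 <= site < H.n_sites):
        raise IndexError("site index out of range")
    if not (0 <= n1 < H.n_templates and 0 <= n2 < H.n_templates):
        raise IndexError("template index out of range")
    gs = {int(g.pairs[site, 0]), int(g.pairs[site, 1])}
    ts = {int(H.alleles[site, n1]), int(H.alleles[site, n2])}
    return len(gs ^ ts)


def diploid_mismatch_count(path1, path2, g: GenotypeSequence, H: AlleleMatrix) -> int:
    """Total diploid mismatch ``m(pi, lambda)`` over the path pair's prefix."""
    s1, s2 = _states(path1), _states(path2)
    if s1.size != s2.size:
        raise ValueError("path lengths differ")
    if s1.size > H.n_sites or s1.size > len(g):
        raise ValueError("paths longer than the data")
    total = 0
    for k in range(s1.size):
        total += diploid_site_mismatch(k, int(s1[k]), int(s2[k]), g, H)
    return total


# ---------------------------------------------------------------------------
# (theta, rho) <-> penalty maps


@dataclass(frozen=True)
class PenaltySpec:
    """Per-site error probability ``p_theta`` and per-transition switch
    probability ``p_rho`` for a panel of ``N`` templates.

    The standing assumption min{alpha, beta} > 0 translates into the
    bounds 0 < p_theta < 1/4 and 0 < p_rho < 1/(N+1), which are enforced
    here.
    """

    N: int
    p_theta: float
    p_rho: float

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("panel size must be positive")
        if not (0.0 < self.p_theta < 0.25):
            raise ValueError(
                f"p_theta={self.p_theta} violates 0 < p_theta < 1/4 (alpha > 0)"
            )
        if not (0.0 < self.p_rho < 1.0 / (self.N + 1)):
            raise ValueError(
                f"p_rho={self.p_rho} violates 0 < p_rho < 1/(N+1) (beta > 0)"
            )

    @property
    def alpha(self) -> float:
        return alpha_from_p(self.p_theta)

    @property
    def beta(self) -> float:
        return beta_from_p(self.p_rho, self.N)

    @property
    def ratio(self) -> float:
        """The penalty ratio c = beta / alpha; the LS decoding depends on
        (theta, rho) only through this number."""
        return self.beta / self.alpha


def p_theta_coalescent(theta: float, N: int) -> float:
    """Genealogical map: p_theta = (1 - exp(-theta/N)) / 3."""
    return (1.0 - math.exp(-theta / N)) / 3.0


def p_theta_original(theta_tilde: float, N: int) -> float:
    """Li and Stephens' original map: p_theta = theta~ / [2(N + theta~)]."""
    return theta_tilde / (2.0 * (N + theta_tilde))


def p_rho_coalescent(rho: float, N: int) -> float:
    """p_rho = (1 - exp(-rho/N)) / N."""
    return (1.0 - math.exp(-rho / N)) / N


def alpha_from_p(p_theta: float) -> float:
    if not (0.0 < p_theta < 0.25):
        raise ValueError(f"p_theta={p_theta} violates 0 < p_theta < 1/4")
    return -math.log(p_theta / (1.0 - 3.0 * p_theta))


def beta_from_p(p_rho: float, N: int) -> float:
    if not (0.0 < p_rho < 1.0 / (N + 1)):
        raise ValueError(f"p_rho={p_rho} violates 0 < p_rho < 1/(N+1)")
    return -math.log(p_rho / (1.0 - N * p_rho))


def alpha(theta: float, N: int, parameterization: str = "coalescent") -> float:
    """Mismatch penalty alpha(theta) = -log[p_theta / (1 - 3 p_theta)].

    ``parameterization`` chooses the map from the mutation rate to
    p_theta: ``"coalescent"`` (default) or ``"original"``.
    Strictly positive and strictly decreasing in theta on its domain.
    """
    if parameterization == "coalescent":
        p = p_theta_coalescent(theta, N)
    elif parameterization == "original":
        p = p_theta_original(theta, N)
    else:
        raise ValueError(f"unknown parameterization {parameterization!r}")
    return alpha_from_p(p)


def beta(rho: float, N: int) -> float:
    """Switch penalty beta(rho) = -log[p_rho / (1 - N p_rho)]."""
    return beta_from_p(p_rho_coalescent(rho, N), N)


def penalty_ratio(theta: float, rho: float, N: int, parameterization: str = "coalescent") -> float:
    """c = beta(rho) / alpha(theta): the single tuning parameter of LS."""
    return beta(rho, N) / alpha(theta, N, parameterization)


def equivalence_curve(c: float, p_theta_grid: Sequence[float], N: int) -> list[tuple[float, float]]:
    """The curve of (p_theta', p_rho') pairs sharing the penalty ratio ``c``.

    For each grid value, p_rho' = 1 / (N + (p_theta'/(1-3 p_theta'))^{-c});
    every returned pair has beta/alpha == c, so the LS output is identical
    along the curve.
    """
    if c <= 0:
        raise ValueError("penalty ratio must be positive")
    out = []
    for pt in p_theta_grid:
        if not (0.0 < pt < 0.25):
            raise ValueError(f"grid p_theta={pt} outside (0, 1/4)")
        pr = 1.0 / (N + (pt / (1.0 - 3.0 * pt)) ** (-c))
        out.append((pt, pr))
    return out


def path_cost(paths, focal, H: AlleleMatrix, c: float) -> float:
    """Normalized LS cost: m + c*k (haploid) or m + c*(k1+k2) (diploid).

    ``paths`` is a single path (haploid, with ``focal`` a Haplotype) or a
    pair of paths (diploid, with ``focal`` a GenotypeSequence).  The
    additive constant of the log-likelihood is dropped.
    """
    if c <= 0:
        raise ValueError("penalty ratio c must be positive")
    if isinstance(focal, GenotypeSequence):
        p1, p2 = paths
        m = diploid_mismatch_count(p1, p2, focal, H)
        k = switch_count(p1) + switch_count(p2)
    else:
        m = mismatch_count(paths, focal, H)
        k = switch_count(paths)
    return m + c * k
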