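"""Slow, independent reference implementations used for validation.

Nothing here is used by the production surface algorithms; these
routines exist so that the exact claims of the surface computation can
be checked by equality (not tolerance) against brute force:

* exhaustive enumeration of all ``N^L`` paths (or all path pairs);
* fixed-penalty Viterbi decoding with exact rational arithmetic
  (``beta = p/q`` is handled by minimizing the integer ``q*m + p*k``);
* the direct ``J_l(r)`` dynamic program over (site, switches, template).
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

from .model import (
    AlleleMatrix,
    CopyPath,
    GenotypeSequence,
    Haplotype,
    diploid_site_mismatch,
)

__all__ = [
    "enumerate_paths",
    "enumerate_haploid_costs",
    "enumerate_diploid_costs",
    "viterbi_haploid",
    "viterbi_diploid",
    "j_table",
]

_INF = np.int64(1) << 40


def enumerate_paths(N: int, L: int) -> np.ndarray:
    """All ``N**L`` copying paths as an array of shape (N**L, L)."""
    if N**L > 2**22:
        raise ValueError("path space too large to enumerate")
    grids = np.meshgrid(*([np.arange(N)] * L), indexing="ij")
    return np.stack(grids, axis=-1).reshape(-1, L)


def enumerate_haploid_costs(h: Haplotype, H: AlleleMatrix) -> np.ndarray:
    """(r, m) for every path, by direct evaluation of the definitions."""
    L, N = H.n_sites, H.n_templates
    paths = enumerate_paths(N, L)
    copied = H.alleles[np.arange(L)[None, :], paths]
    m = (copied != h.alleles[None, :]).sum(axis=1)
    r = (paths[:, 1:] != paths[:, :-1]).sum(axis=1) if L > 1 else np.zeros(len(paths), dtype=np.int64)
    return np.stack([r, m], axis=1).astype(np.int64)


def pair_mismatch_matrix(site: int, g: GenotypeSequence, H: AlleleMatrix) -> np.ndarray:
    """N x N matrix of per-site diploid mismatches, literal set semantics."""
    N = H.n_templates
    D = np.empty((N, N), dtype=np.int64)
    for n1 in range(N):
        for n2 in range(n1, N):
            v = diploid_site_mismatch(site, n1, n2, g, H)
            D[n1, n2] = v
            D[n2, n1] = v
    return D


def enumerate_diploid_costs(g: GenotypeSequence, H: AlleleMatrix) -> np.ndarray:
    """(r1+r2, m) for every ordered pair of paths."""
    L, N = H.n_sites, H.n_templates
    if N ** (2 * L) > 2**22:
        raise ValueError("pair space too large to enumerate")
    paths = enumerate_paths(N, L)
    P = len(paths)
    r = (paths[:, 1:] != paths[:, :-1]).sum(axis=1) if L > 1 else np.zeros(P, dtype=np.int64)
    r_pair = r[:, None] + r[None, :]
    m_pair = np.zeros((P, P), dtype=np.int64)
    for site in range(L):
        D = pair_mismatch_matrix(site, g, H)
        col = paths[:, site]
        m_pair += D[col[:, None], col[None, :]]
    return np.stack([r_pair.ravel(), m_pair.ravel()], axis=1)


def _beta_parts(beta) -> tuple[int, int]:
    b = beta if isinstance(beta, Fraction) else Fraction(beta)
    if b <= 0:
        raise ValueError("beta must be positive")
    return b.numerator, b.denominator


def viterbi_haploid(h: Haplotype, H: AlleleMatrix, beta) -> tuple[CopyPath, Fraction]:
    """Exact fixed-penalty Viterbi: minimal ``m + beta*k`` and an argmin path.

    For rational ``beta = p/q`` the integer objective ``q*m + p*k`` is
    minimized, so the result is exact.
    """
    p, q = _beta_parts(beta)
    L, N = H.n_sites, H.n_templates
    hv, Hm = h.alleles, H.alleles
    V = q * (hv[0] != Hm[0]).astype(np.int64)
    back = np.full((L, N), -1, dtype=np.int64)  # -1 = stayed
    for site in range(1, L):
        vmin = V.min()
        amin = int(V.argmin())
        switch = vmin + p
        d = q * (hv[site] != Hm[site]).astype(np.int64)
        sw = switch < V  # strict: ties prefer staying
        back[site, sw] = amin
        V = d + np.where(sw, switch, V)
    end = int(V.argmin())
    states = np.empty(L, dtype=np.int64)
    states[L - 1] = end
    n = end
    for site in range(L - 1, 0, -1):
        prev = back[site, n]
        n = n if prev < 0 else int(prev)
        states[site - 1] = n
    return CopyPath(states), Fraction(int(V.min()), q)


def viterbi_diploid(g: GenotypeSequence, H: AlleleMatrix, beta) -> tuple[tuple[CopyPath, CopyPath], Fraction]:
    """Exact fixed-penalty Viterbi over ordered path pairs.

    O(L * N^2) per site via the row-min / column-min / global-min
    decomposition of the pair transition cost.
    """
    p, q = _beta_parts(beta)
    L, N = H.n_sites, H.n_templates
    D = [pair_mismatch_matrix(site, g, H) for site in range(L)]
    V = q * D[0]
    layers = [V]
    for site in range(1, L):
        row = V.min(axis=1, keepdims=True)  # best over second coordinate
        col = V.min(axis=0, keepdims=True)
        glob = V.min()
        best = np.minimum(np.minimum(V, row + p), np.minimum(col + p, glob + 2 * p))
        V = q * D[site] + best
        layers.append(V)
    n1, n2 = np.unravel_index(int(V.argmin()), V.shape)
    s1 = np.empty(L, dtype=np.int64)
    s2 = np.empty(L, dtype=np.int64)
    s1[L - 1], s2[L - 1] = n1, n2
    for site in range(L - 1, 0, -1):
        target = layers[site][n1, n2] - q * D[site][n1, n2]
        Vp = layers[site - 1]
        if Vp[n1, n2] == target:
            pass  # both stayed
        else:
            found = False
            for j in range(N):  # second coordinate switched
                if j != n2 and Vp[n1, j] + p == target:
                    n2 = j
                    found = True
                    break
            if not found:
                for i in range(N):  # first coordinate switched
                    if i != n1 and Vp[i, n2] + p == target:
                        n1 = i
                        found = True
                        break
            if not found:  # both switched
                for i in range(N):
                    for j in range(N):
                        if i != n1 and j != n2 and Vp[i, j] + 2 * p == target:
                            n1, n2 = i, j
                            found = True
                            break
                    if found:
                        break
            if not found:
                raise RuntimeError("backtrace failed")
        s1[site - 1], s2[site - 1] = n1, n2
    return (CopyPath(s1), CopyPath(s2)), Fraction(int(layers[-1].min()), q)


def j_table(h: Haplotype, H: AlleleMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Direct DP for ``J_L^{(n)}(r)``: minimal mismatches among paths with
    exactly ``r`` switches ending at template ``n``.

    Returns ``(J, Jmin)`` where ``J[n, r]`` is the per-template table and
    ``Jmin[r] = min_n J[n, r]``; infeasible ``r > L-1`` cells hold a large
    sentinel.
    """
    L, N = H.n_sites, H.n_templates
    hv, Hm = h.alleles, H.alleles
    J = np.full((N, L), _INF, dtype=np.int64)
    J[:, 0] = (hv[0] != Hm[0]).astype(np.int64)
    for site in range(1, L):
        d = (hv[site] != Hm[site]).astype(np.int64)
        jmin = J.min(axis=0)
        shifted = np.empty(L, dtype=np.int64)
        shifted[0] = _INF
        shifted[1:] = jmin[:-1]
        J = np.minimum(J, shifted[None, :])
        feasible = J < _INF
        J = np.where(feasible, J + d[:, None], _INF)
    return J, J.min(axis=0)
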