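"""Single-pass computation of all haploid LS decodings.

As the switch penalty ``beta`` sweeps ``(0, inf)`` the Viterbi decoding
of the LS model changes only finitely many times.  Each optimal decoding
corresponds to a vertex of the lower convex hull of the set
``{(k(pi), m(pi))}`` over all copying paths, and the penalty values at
which the optimum jumps are the exact rational slopes between adjacent
hull vertices.

The algorithm sweeps the sites once.  At site ``l`` it maintains, for
every template ``n``, the hull chain of cost points achievable by paths
ending at ``n`` (the *locally active* paths), plus the global chain (the
*active* paths).  Moving to site ``l+1`` a path ending at ``n`` either
stays on ``n`` (cost unchanged except the new mismatch indicator) or
switches onto ``n`` from the globally best frontier (one extra switch).
Only hull vertices can have optimal extensions, so the frontier stays
small, and since every quantity is an integer the computation is exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

from .hull import (
    CostPoint,
    chain_to_json,
    lower_left_hull,
    region_for_beta,
    regions_from_breakpoints,
    theorem2_breakpoints,
)
from .model import AlleleMatrix, CopyPath, Haplotype

__all__ = ["SolutionSurface", "partition_haploid", "mismatch_indicator", "reconstruct_path"]


def mismatch_indicator(site: int, template: int, h: Haplotype, H: AlleleMatrix) -> int:
    """d_l(n): 1 if the focal allele at ``site`` differs from template
    ``n``'s allele, else 0."""
    if not (0 <= site < H.n_sites):
        raise IndexError("site index out of range")
    if not (0 <= template < H.n_templates):
        raise IndexError("template index out of range")
    return int(h.alleles[site] != H.alleles[site, template])


@dataclass(frozen=True)
class SolutionSurface:
    """The full solution surface of one decoding problem.

    ``vertices[i]`` is the i-th hull vertex (decreasing beta order: r
    increases, m decreases); ``breakpoints`` are the exact rationals at
    which the optimum changes; ``regions[i]`` is the half-open beta
    interval (lo, hi), ``hi=None`` meaning +infinity, on which vertex i
    is optimal; ``representative_paths[i]`` is one optimal path (or path
    pair, in the diploid case) attaining vertex i's cost coordinates.
    """

    vertices: tuple
    breakpoints: tuple
    representative_paths: tuple
    diploid: bool = False

    @property
    def regions(self):
        return regions_from_breakpoints(self.breakpoints)

    def vertex_coords(self) -> list[tuple[int, int]]:
        return [v.coords() for v in self.vertices]

    def optimal_vertex(self, beta) -> tuple[int, bool]:
        """(index, tie flag) of the optimal vertex at penalty ``beta``."""
        return region_for_beta(self.vertices, self.breakpoints, beta)

    def cost_at(self, beta) -> Fraction:
        """Exact optimal cost min_i m_i + beta * r_i at rational ``beta``."""
        if not isinstance(beta, Fraction):
            beta = Fraction(beta)
        return min(v.m + beta * v.r for v in self.vertices)

    def to_json(self, paths: bool = False) -> dict:
        out = chain_to_json(self.vertices, self.breakpoints)
        out["regions"] = [
            [None if lo == 0 else [lo.numerator, lo.denominator],
             None if hi is None else [hi.numerator, hi.denominator]]
            for lo, hi in self.regions
        ]
        if paths:
            if self.diploid:
                out["paths"] = [
                    [_rle(p1.states), _rle(p2.states)]
                    for p1, p2 in self.representative_paths
                ]
            else:
                out["paths"] = [_rle(p.states) for p in self.representative_paths]
        return out


def _rle(states: np.ndarray) -> list[list[int]]:
    """Run-length encode a path as [start_site, template] segments."""
    segs = []
    for i, s in enumerate(states):
        if not segs or segs[-1][1] != int(s):
            segs.append([i, int(s)])
    return segs


def _merge_global(F: list[list[CostPoint]]) -> list[CostPoint]:
    # Global chain vertices carry (template, local vertex) provenance;
    # candidate order (ascending template) makes ties resolve to the
    # lowest template index.
    pooled = [CostPoint(p.r, p.m, (n, p)) for n, chain in enumerate(F) for p in chain]
    return lower_left_hull(pooled)


def partition_haploid(h: Haplotype, H: AlleleMatrix) -> SolutionSurface:
    """Compute the complete haploid solution surface in one pass.

    Returns the hull vertices of ``{(k(pi), m(pi))}``, the rational
    breakpoints partitioning ``(0, inf)`` into constant-decoding regions,
    and one representative optimal path per vertex.
    """
    if not isinstance(h, Haplotype):
        h = Haplotype(np.asarray(h))
    L, N = H.n_sites, H.n_templates
    if len(h) != L:
        raise ValueError("focal haplotype length does not match the panel")
    hv = h.alleles
    Hm = H.alleles

    # Site 0: only constant length-1 paths exist, each with r=0.
    d0 = (hv[0] != Hm[0]).astype(np.int64)
    F = [[CostPoint(0, int(d0[n]), None)] for n in range(N)]
    G = _merge_global(F)

    for site in range(1, L):
        d = (hv[site] != Hm[site]).astype(np.int64)
        newF = []
        for n in range(N):
            dn = int(d[n])
            # No-switch extensions first so ties prefer fewer switches.
            cands = [CostPoint(p.r, p.m + dn, ("S", p)) for p in F[n]]
            cands += [
                CostPoint(q.r + 1, q.m + dn, ("X", q.prov[0], q.prov[1]))
                for q in G
            ]
            newF.append(lower_left_hull(cands))
        F = newF
        G = _merge_global(F)

    bps = theorem2_breakpoints(G)
    paths = tuple(
        CopyPath(_walk_back(G[i], L)) for i in range(len(G))
    )
    return SolutionSurface(
        vertices=tuple(G), breakpoints=tuple(bps), representative_paths=paths
    )


def _walk_back(gvert: CostPoint, L: int) -> np.ndarray:
    """Follow backpointers from a global vertex to a concrete path."""
    n, fv = gvert.prov
    states = np.empty(L, dtype=np.int64)
    site = L - 1
    while True:
        states[site] = n
        src = fv.prov
        if src is None:
            break
        if src[0] == "S":
            fv = src[1]
        else:  # ("X", previous template, parent local vertex)
            _, n, fv = src
        site -= 1
    if site != 0:
        raise RuntimeError("corrupted provenance: path does not span all sites")
    return states


def reconstruct_path(surface: SolutionSurface, index: int) -> CopyPath:
    """Representative optimal path for vertex ``index`` of the surface."""
    return surface.representative_paths[index]
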