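"""Solution surface for unphased diplotypes: pairs of copying paths.

The diploid LS decoding finds a pair of copying paths ``(pi, lambda)``
minimizing ``m(pi, lambda) + beta * (k(pi) + k(lambda))``, where the
mismatch term compares the unordered genotype at each site with the
unordered pair of copied template alleles.  The frontier sweep mirrors
the haploid algorithm, but the local state is richer: per unordered
template pair ``(n1, n2)`` a chain of *locally active* pair costs; per
single template ``n`` a chain of *partially active* costs (best over all
pairs containing ``n``), feeding single-switch extensions; and the
global chain feeding double-switch extensions.  Extending to a new site,
a pair either keeps both templates (no new switch), keeps one and
switches the other (one new switch, fed by the partial chains), or
switches both (two new switches, fed by the global chain).

Genotypes are unphased, so the pair state space is the set of unordered
pairs ``n1 <= n2``; this halves the work and makes the output invariant
under swapping the two alleles of any genotype.
"""

from __future__ import annotations

import numpy as np

from .hull import CostPoint, lower_left_hull, theorem2_breakpoints
from .haploid import SolutionSurface
from .model import (
    AlleleMatrix,
    CopyPath,
    GenotypeSequence,
    Haplotype,
    diploid_site_mismatch,
)

__all__ = ["partition_diploid", "phase_from_pair", "pair_mismatch_matrix"]


def pair_mismatch_matrix(site: int, g: GenotypeSequence, H: AlleleMatrix) -> np.ndarray:
    """N x N matrix of per-site diploid mismatches |{g} sym-diff {copies}|.

    Vectorized dosage form for biallelic data (provably identical to the
    set form there); literal set semantics otherwise.
    """
    N = H.n_templates
    row = H.alleles[site]
    if len(H.alphabet) == 2:
        dose = int(g.pairs[site, 0] + g.pairs[site, 1])
        return np.abs(dose - (row[:, None] + row[None, :])).astype(np.int64)
    D = np.empty((N, N), dtype=np.int64)
    for n1 in range(N):
        for n2 in range(n1, N):
            v = diploid_site_mismatch(site, n1, n2, g, H)
            D[n1, n2] = v
            D[n2, n1] = v
    return D


def partition_diploid(g: GenotypeSequence, H: AlleleMatrix) -> SolutionSurface:
    """Complete diploid solution surface in one pass over the sites."""
    L, N = H.n_sites, H.n_templates
    if len(g) != L:
        raise ValueError("genotype length does not match the panel")

    pairs = [(n1, n2) for n1 in range(N) for n2 in range(n1, N)]
    pair_index = {pr: i for i, pr in enumerate(pairs)}

    D = pair_mismatch_matrix(0, g, H)
    # Site 0: one cost point per pair, no switches yet.
    F = [[CostPoint(0, int(D[n1, n2]), None)] for (n1, n2) in pairs]
    P, G = _merge_partials(F, pairs, N)

    for site in range(1, L):
        D = pair_mismatch_matrix(site, g, H)
        newF = []
        for (n1, n2) in pairs:
            d = int(D[n1, n2])
            fch = F[pair_index[(n1, n2)]]
            # Candidate order encodes tie preference: fewer new switches
            # first, then the lower continuing template.
            cands = [CostPoint(p.r, p.m + d, ("S", p)) for p in fch]
            for (r, m, pr, fv) in P[n1]:
                # coordinate at n1 continues; the other switches onto n2
                prev_other = pr[1] if pr[0] == n1 else pr[0]
                cands.append(CostPoint(r + 1, m + d, ("H", n1, prev_other, pr, fv)))
            for (r, m, pr, fv) in P[n2]:
                prev_other = pr[1] if pr[0] == n2 else pr[0]
                cands.append(CostPoint(r + 1, m + d, ("H", n2, prev_other, pr, fv)))
            for (r, m, pr, fv) in G:
                cands.append(CostPoint(r + 2, m + d, ("D", pr, fv)))
            newF.append(lower_left_hull(cands))
        F = newF
        P, G = _merge_partials(F, pairs, N)

    # Final global chain with (pair, local vertex) provenance.
    final = lower_left_hull(
        [CostPoint(p.r, p.m, (pr, p)) for pr, ch in zip(pairs, F) for p in ch]
    )
    bps = theorem2_breakpoints(final)
    rep = tuple(_walk_back_pair(v, L) for v in final)
    return SolutionSurface(
        vertices=tuple(final), breakpoints=tuple(bps),
        representative_paths=rep, diploid=True,
    )


def _merge_partials(F, pairs, N):
    """Rebuild partial chains P[n] and the global chain G from the local
    pair chains.  Entries are (r, m, pair, local vertex) tuples."""
    per_n: list[list] = [[] for _ in range(N)]
    pooled: list[CostPoint] = []
    for pr, ch in zip(pairs, F):
        n1, n2 = pr
        for p in ch:
            per_n[n1].append(CostPoint(p.r, p.m, (pr, p)))
            if n2 != n1:
                per_n[n2].append(CostPoint(p.r, p.m, (pr, p)))
            pooled.append(CostPoint(p.r, p.m, (pr, p)))
    P = []
    for n in range(N):
        hull = lower_left_hull(per_n[n])
        P.append([(q.r, q.m, q.prov[0], q.prov[1]) for q in hull])
    Ghull = lower_left_hull(pooled)
    G = [(q.r, q.m, q.prov[0], q.prov[1]) for q in Ghull]
    return P, G


def _walk_back_pair(gvert: CostPoint, L: int) -> tuple[CopyPath, CopyPath]:
    """Backpointer walk recovering a concrete ordered path pair."""
    (u, v), fv = gvert.prov
    s1 = np.empty(L, dtype=np.int64)
    s2 = np.empty(L, dtype=np.int64)
    site = L - 1
    while True:
        s1[site], s2[site] = u, v
        src = fv.prov
        if src is None:
            break
        kind = src[0]
        if kind == "S":
            fv = src[1]
        elif kind == "H":
            _, cont, prev_other, pr, fv = src
            # the coordinate currently at `cont` continues; the other
            # coordinate switched from prev_other
            if u == cont:
                u, v = cont, prev_other
            elif v == cont:
                u, v = prev_other, cont
            else:  # pragma: no cover - provenance corruption
                raise RuntimeError("corrupted provenance in half-switch")
        else:  # "D": both coordinates switched
            _, pr, fv = src
            a, b = pr
            if a != u and b != v:
                u, v = a, b
            elif b != u and a != v:
                u, v = b, a
            else:  # pragma: no cover - dominated candidates cannot survive
                raise RuntimeError("double-switch provenance without two switches")
        site -= 1
    if site != 0:
        raise RuntimeError("corrupted provenance: pair does not span all sites")
    return CopyPath(s1), CopyPath(s2)


def phase_from_pair(pair: tuple[CopyPath, CopyPath], H: AlleleMatrix) -> tuple[Haplotype, Haplotype]:
    """Emit the two phased haplotypes implied by a copying-path pair.

    Haplotype j's allele at each site is the allele of the template it
    copies there.  At sites where the copied alleles do not reproduce the
    genotype (mismatch sites) the template alleles are emitted as copied;
    downstream switch-error evaluation excludes such discordant sites.
    """
    p1, p2 = pair
    idx = np.arange(H.n_sites)
    h1 = Haplotype(H.alleles[idx, p1.states])
    h2 = Haplotype(H.alleles[idx, p2.states])
    return h1, h2
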