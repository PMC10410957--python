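"""Self-contained synthetic data generators and coalescent hooks.

Two panel generators are provided:

``mosaic``
    A PAC-style sequential construction: each new haplotype is an
    LS-style copy of the previously generated ones, with per-transition
    switch probability ``N * p_rho`` and per-site copying-error
    probability ``p_theta``.  This produces panels with realistic
    linkage-disequilibrium block structure and a decreasing site
    frequency spectrum without requiring an ancestral-recombination-graph
    simulator.

``iid``
    Sites are independent; each site's allele frequency is drawn from
    the neutral ``1/i`` spectrum and entries are Bernoulli.  Useful for
    quick unstructured tests.

For full coalescent panels :func:`coalescent_panel` wraps msprime, and
:func:`expansion_demography` builds a simplified two-epoch
recent-expansion model — a synthetic stand-in for a realistic human
demography, *not* a published calibrated model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import AlleleMatrix, CopyPath, GenotypeSequence, Haplotype

__all__ = [
    "GenerativeConfig",
    "generate_panel",
    "sample_focal",
    "sample_diplotype",
    "mask_by_maf",
    "expected_maf_retention",
    "coalescent_panel",
    "expansion_demography",
    "expected_pairwise_tmrca",
]


@dataclass(frozen=True)
class GenerativeConfig:
    """Study conditions for the self-contained generators.

    ``p_theta`` / ``p_rho`` are the LS generative probabilities (per
    site / per transition); ``maf_threshold`` is the minor-allele
    frequency below which sites are masked (0.05 as in the evaluation
    protocol).  A seed is mandatory: every generator is a pure function
    of (config, seed).
    """

    N: int
    L: int
    p_theta: float = 1e-3
    p_rho: float = 1e-4
    seed: int = 0
    panel_model: str = "mosaic"
    maf_threshold: float = 0.05

    def __post_init__(self):
        if not (0.0 < self.p_theta < 0.25):
            raise ValueError("p_theta outside (0, 1/4)")
        if not (0.0 < self.p_rho < 1.0 / (self.N + 1)):
            raise ValueError("p_rho outside (0, 1/(N+1))")
        if self.panel_model not in ("mosaic", "iid"):
            raise ValueError("panel_model must be 'mosaic' or 'iid'")


def _mosaic_block(rng: np.random.Generator, N: int, L: int, p_theta: float, p_rho: float) -> np.ndarray:
    """One raw (pre-filter) mosaic panel block of shape (L, N)."""
    H = np.zeros((L, N), dtype=np.int64)
    # Founder haplotype: sparse derived alleles on a null background.
    H[:, 0] = rng.random(L) < p_theta
    switch_p = min(1.0, N * p_rho)
    for k in range(1, N):
        # copy from columns 0..k-1 with LS switching, then flip errors
        src = np.empty(L, dtype=np.int64)
        cur = int(rng.integers(k))
        resample = rng.random(L) < switch_p
        for site in range(L):
            if site > 0 and resample[site]:
                cur = int(rng.integers(k))
            src[site] = cur
        hap = H[np.arange(L), src]
        flip = rng.random(L) < p_theta
        H[:, k] = np.where(flip, 1 - hap, hap)
    return H


def generate_panel(config: GenerativeConfig) -> AlleleMatrix:
    """Deterministic (given seed) biallelic panel with every site segregating.

    The mosaic model accumulates raw blocks until ``L`` segregating
    sites have been collected, then truncates; the iid model draws site
    frequencies from the neutral spectrum.
    """
    rng = np.random.default_rng(config.seed)
    N, L = config.N, config.L
    if config.panel_model == "iid":
        i = np.arange(1, N)
        probs = (1.0 / i) / np.sum(1.0 / i)
        freqs = rng.choice(i, size=L, p=probs) / N
        H = (rng.random((L, N)) < freqs[:, None]).astype(np.int64)
        # enforce segregation: flip one entry at monomorphic sites
        for site in np.nonzero(H.sum(1) % N == 0)[0]:
            H[site, rng.integers(N)] ^= 1
        return AlleleMatrix(H)
    rows = []
    total = 0
    # expected segregating fraction ~ N * p_theta per site; draw blocks
    block = max(L, int(math.ceil(L / max(N * config.p_theta, 1e-6))))
    block = min(block, 500_000)
    for _ in range(64):
        raw = _mosaic_block(rng, N, block, config.p_theta, config.p_rho)
        seg = raw[(raw.sum(axis=1) > 0) & (raw.sum(axis=1) < N)]
        rows.append(seg)
        total += len(seg)
        if total >= L:
            break
    else:
        raise RuntimeError(
            "segregating sites accumulate too slowly; increase p_theta or L budget"
        )
    H = np.concatenate(rows)[:L]
    return AlleleMatrix(H)


def sample_focal(H: AlleleMatrix, p_theta: float, p_rho: float, seed: int) -> tuple[Haplotype, CopyPath]:
    """Draw a focal haplotype from the LS generative process.

    The latent path is a stationary Markov chain: with probability
    ``N * p_rho`` the template is resampled uniformly (a resample that
    lands on the same template is not a switch); the focal allele copies
    the template allele, flipped with probability ``p_theta`` (biallelic)
    or mutated uniformly to one of the other alleles (larger alphabets).
    Returns both the haplotype and the latent truth path.
    """
    rng = np.random.default_rng(seed)
    L, N = H.n_sites, H.n_templates
    if not (0.0 < p_rho < 1.0 / (N + 1)):
        raise ValueError("p_rho outside (0, 1/(N+1))")
    if not (0.0 < p_theta < 0.25):
        raise ValueError("p_theta outside (0, 1/4)")
    switch_p = N * p_rho
    states = np.empty(L, dtype=np.int64)
    cur = int(rng.integers(N))
    resample = rng.random(L) < switch_p
    draws = rng.integers(0, N, size=L)
    for site in range(L):
        if site > 0 and resample[site]:
            cur = int(draws[site])
        states[site] = cur
    hap = H.alleles[np.arange(L), states].copy()
    err = rng.random(L) < p_theta
    A = len(H.alphabet)
    if A == 2:
        hap[err] = 1 - hap[err]
    else:
        shift = rng.integers(1, A, size=L)
        hap[err] = (hap[err] + shift[err]) % A
    return Haplotype(hap), CopyPath(states)


def sample_diplotype(H: AlleleMatrix, p_theta: float, p_rho: float, seed: int):
    """Two independent LS draws combined into an unphased diplotype.

    Returns (genotypes, (h1, h2), (path1, path2))."""
    h1, p1 = sample_focal(H, p_theta, p_rho, seed)
    h2, p2 = sample_focal(H, p_theta, p_rho, seed + 1)
    return GenotypeSequence.from_haplotypes(h1, h2), (h1, h2), (p1, p2)


def mask_by_maf(columns: np.ndarray, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Split sites into retained / masked by minor allele frequency.

    ``columns`` is the full biallelic sample (sites x chromosomes),
    *including* the focal chromosome(s): the filter is applied to the
    simulated sample before the focal/panel split.  Sites with
    MAF >= threshold are retained.  Both index lists are increasing.
    """
    arr = np.asarray(columns)
    if arr.ndim != 2:
        raise ValueError("expected a sites x chromosomes matrix")
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValueError("MAF masking requires biallelic (0/1) data")
    n = arr.shape[1]
    count = arr.sum(axis=1)
    maf = np.minimum(count, n - count) / n
    keep = maf >= threshold
    return np.nonzero(keep)[0], np.nonzero(~keep)[0]


def expected_maf_retention(n: int, threshold: float) -> float:
    """Neutral-SFS probability that a segregating site passes the MAF filter.

    Under the standard neutral site-frequency spectrum a segregating
    site has derived count ``i`` with probability proportional to
    ``1/i``; the retained fraction is the normalized harmonic mass of
    the counts with ``min(i, n-i)/n >= threshold``.
    """
    if n < 2:
        raise ValueError("need at least two chromosomes")
    if not (0.0 < threshold <= 0.5):
        raise ValueError("threshold must be in (0, 0.5]")
    i = np.arange(1, n)
    w = 1.0 / i
    keep = np.minimum(i, n - i) / n >= threshold
    return float(w[keep].sum() / w.sum())


# ---------------------------------------------------------------------------
# Coalescent hooks (msprime)


def coalescent_panel(
    n_haplotypes: int,
    sequence_length: float,
    mutation_rate: float,
    recombination_rate: float,
    seed: int,
    demography=None,
) -> AlleleMatrix:
    """Simulate a biallelic haplotype matrix with msprime.

    Haploid samples from a single population (size 1 unless a demography
    is supplied), binary mutations.  Returns sites x haplotypes with
    physical positions attached.
    """
    import msprime

    kwargs = dict(
        samples=n_haplotypes,
        ploidy=1,
        sequence_length=sequence_length,
        recombination_rate=recombination_rate,
        random_seed=seed % (2**31 - 2) + 1,
    )
    if demography is None:
        kwargs["population_size"] = 1.0
    else:
        kwargs["demography"] = demography
    ts = msprime.sim_ancestry(**kwargs)
    ts = msprime.sim_mutations(
        ts,
        rate=mutation_rate,
        random_seed=seed % (2**31 - 2) + 1,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
    )
    G = ts.genotype_matrix()
    pos = np.array([s.position for s in ts.sites()])
    seg = (G.sum(axis=1) > 0) & (G.sum(axis=1) < n_haplotypes)
    return AlleleMatrix(G[seg].astype(np.int64), positions=pos[seg])


def expansion_demography(
    recent_size: float = 58.0,
    mid_size: float = 2.0,
    old_size: float = 1.0,
    t_growth: float = 0.02,
    t_old: float = 0.81,
):
    """Synthetic single-population demography with African-like shape.

    Recent explosive exponential growth (``mid_size`` to ``recent_size``
    over the last ``t_growth`` time units), a moderate middle epoch, and
    a smaller ancestral size — the qualitative shape of human African
    demographic history, expressed in units of the ancestral size.  A
    desk-scale stand-in, not a calibrated published model.
    """
    import msprime

    dem = msprime.Demography()
    dem.add_population(
        initial_size=recent_size,
        growth_rate=math.log(recent_size / mid_size) / t_growth,
    )
    dem.add_population_parameters_change(time=t_growth, initial_size=mid_size, growth_rate=0)
    dem.add_population_parameters_change(time=t_old, initial_size=old_size)
    return dem


def expected_pairwise_tmrca(demography=None) -> float:
    """E[T2] (generations) for a demography; 1.0 for the constant-size
    default.  Used to form the population-scaled rates theta = 4*Ne*mu
    with Ne = E[T_MRCA]/2."""
    if demography is None:
        return 1.0
    dbg = demography.debug()
    name = demography.populations[0].name
    return float(dbg.mean_coalescence_time(lineages={name: 2}))
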