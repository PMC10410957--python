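"""Imputation-error and phasing-switch-error studies over the surface.

Both evaluation pipelines exercise the solution surface end to end: the
loss (imputation error or switch error) is evaluated once per constant-
decoding region using that region's representative optimal path, giving
a piecewise-constant loss-versus-beta curve.  The beta interval on which
the loss is minimal is then compared with the reference penalty implied
by the population-scaled mutation and recombination rates: if the
reference falls inside the optimal interval, running LS "at the truth"
was also optimal for the downstream task.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .diploid import partition_diploid, phase_from_pair
from .haploid import SolutionSurface, partition_haploid
from .model import (
    AlleleMatrix,
    GenotypeSequence,
    Haplotype,
    alpha_from_p,
    beta_from_p,
    penalty_ratio,
)
from .simulate import (
    GenerativeConfig,
    coalescent_panel,
    expansion_demography,
    expected_pairwise_tmrca,
    generate_panel,
    mask_by_maf,
    sample_focal,
)

__all__ = [
    "impute_from_path",
    "imputation_loss",
    "maf_weights",
    "RegionLossCurve",
    "OptimalInterval",
    "loss_curve",
    "optimal_interval",
    "SwitchError",
    "switch_error",
    "StudyConfig",
    "run_imputation_replicates",
    "run_phasing_replicates",
    "summarize_fraction_optimal",
]


def impute_from_path(path, retained: np.ndarray, masked: np.ndarray, H_full: AlleleMatrix) -> np.ndarray:
    """Impute masked sites by pasting the copying state from the nearest
    retained marker (index distance; ties go left; sites before the first
    marker use the first)."""
    retained = np.asarray(retained)
    masked = np.asarray(masked)
    if retained.size == 0:
        raise ValueError("no retained sites to copy from")
    states = path.states if hasattr(path, "states") else np.asarray(path)
    if states.size != retained.size:
        raise ValueError("path must be defined on the retained sites")
    if masked.size == 0:
        return np.empty(0, dtype=np.int64)
    pos = np.searchsorted(retained, masked)
    left = np.clip(pos - 1, 0, retained.size - 1)
    right = np.clip(pos, 0, retained.size - 1)
    dl = np.where(pos > 0, masked - retained[left], np.iinfo(np.int64).max)
    dr = np.where(pos < retained.size, retained[right] - masked, np.iinfo(np.int64).max)
    nearest = np.where(dl <= dr, left, right)  # tie -> left flank
    templates = states[nearest]
    return H_full.alleles[masked, templates]


def imputation_loss(true_alleles, imputed_alleles, weights=None) -> float:
    """Weighted allele disagreement sum; unit weights give Hamming loss."""
    t = np.asarray(true_alleles, dtype=np.int64)
    x = np.asarray(imputed_alleles, dtype=np.int64)
    if t.shape != x.shape:
        raise ValueError("length mismatch")
    diff = np.abs(t - x)
    if weights is None:
        return float(diff.sum())
    w = np.asarray(weights, dtype=float)
    if w.shape != t.shape or np.any(w <= 0):
        raise ValueError("weights must be positive, one per site")
    return float((w * diff).sum())


def maf_weights(full_columns: np.ndarray, sites: np.ndarray) -> np.ndarray:
    """Inverse-variance weights 1/[MAF(1-MAF)] at the given sites, with
    MAF from the full (pre-masking) sample."""
    arr = np.asarray(full_columns)
    n = arr.shape[1]
    count = arr[sites].sum(axis=1)
    maf = np.minimum(count, n - count) / n
    if np.any(maf == 0):
        raise ValueError("cannot weight a non-segregating site (MAF = 0)")
    return 1.0 / (maf * (1.0 - maf))


@dataclass(frozen=True)
class RegionLossCurve:
    """Piecewise-constant loss over the surface's beta regions.

    ``records[i] = (interval, vertex (r, m), loss)`` with intervals in
    decreasing-beta order tiling (0, inf)."""

    records: tuple
    loss_kind: str

    def losses(self) -> np.ndarray:
        return np.array([rec[2] for rec in self.records], dtype=float)


@dataclass(frozen=True)
class OptimalInterval:
    """Union of contiguous minimal-loss regions.

    ``runs`` holds every maximal run as (lo, hi) rational-or-None bounds;
    ``lo``/``hi`` describe the primary run (smallest lower bound);
    ``multimodal`` flags non-contiguous minima."""

    lo: Fraction
    hi: Fraction | None
    loss: float
    contains_reference_beta: bool
    runs: tuple
    multimodal: bool


def loss_curve(surface: SolutionSurface, loss_of_path, loss_kind: str) -> RegionLossCurve:
    """Evaluate ``loss_of_path(representative path or pair)`` once per region."""
    records = []
    for (lo, hi), vertex, path in zip(
        surface.regions, surface.vertices, surface.representative_paths
    ):
        records.append(((lo, hi), vertex.coords(), float(loss_of_path(path))))
    return RegionLossCurve(records=tuple(records), loss_kind=loss_kind)


def _contains(lo, hi, c: Fraction) -> bool:
    return (c >= lo) and (hi is None or c < hi)


def optimal_interval(curve: RegionLossCurve, reference_c) -> OptimalInterval:
    """Maximal union(s) of contiguous regions attaining the minimal loss.

    If the minimum is attained on non-contiguous regions all maximal
    runs are reported and the result is flagged multimodal; the primary
    run is the one with the smallest beta lower bound.  The reference
    penalty ratio is tested against the primary run."""
    losses = curve.losses()
    lmin = losses.min()
    opt = losses == lmin
    runs = []
    i = 0
    M = len(losses)
    while i < M:
        if opt[i]:
            j = i
            while j + 1 < M and opt[j + 1]:
                j += 1
            # regions are in decreasing-beta order: run i..j spans
            # [lo_j, hi_i)
            lo = curve.records[j][0][0]
            hi = curve.records[i][0][1]
            runs.append((lo, hi))
            i = j + 1
        else:
            i += 1
    primary = min(runs, key=lambda run: run[0])
    c = reference_c if isinstance(reference_c, Fraction) else Fraction(reference_c)
    return OptimalInterval(
        lo=primary[0],
        hi=primary[1],
        loss=float(lmin),
        contains_reference_beta=_contains(primary[0], primary[1], c),
        runs=tuple(runs),
        multimodal=len(runs) > 1,
    )


@dataclass(frozen=True)
class SwitchError:
    """Phase switch error between a truth and an estimated haplotype pair.

    Evaluated on sites heterozygous in both pairs with matching allele
    sets (discordant sites are excluded, following the vcftools
    --diff-switch-error convention); a global swap of either pair is not
    an error.  ``rate`` is None when no comparable site exists."""

    count: int
    n_comparable: int
    rate: float | None


def switch_error(truth_pair, estimated_pair) -> SwitchError:
    t1 = np.asarray(truth_pair[0].alleles if hasattr(truth_pair[0], "alleles") else truth_pair[0])
    t2 = np.asarray(truth_pair[1].alleles if hasattr(truth_pair[1], "alleles") else truth_pair[1])
    e1 = np.asarray(estimated_pair[0].alleles if hasattr(estimated_pair[0], "alleles") else estimated_pair[0])
    e2 = np.asarray(estimated_pair[1].alleles if hasattr(estimated_pair[1], "alleles") else estimated_pair[1])
    if not (t1.shape == t2.shape == e1.shape == e2.shape):
        raise ValueError("all four haplotypes must have equal length")
    het = (t1 != t2) & (e1 != e2)
    same_alleles = (np.minimum(t1, t2) == np.minimum(e1, e2)) & (
        np.maximum(t1, t2) == np.maximum(e1, e2)
    )
    comp = het & same_alleles
    orient = e1[comp] == t1[comp]
    count = int(np.count_nonzero(orient[1:] != orient[:-1]))
    K = int(comp.sum())
    if K == 0:
        return SwitchError(count=0, n_comparable=0, rate=None)
    rate = count / (K - 1) if K > 1 else 0.0
    return SwitchError(count=count, n_comparable=K, rate=rate)


# ---------------------------------------------------------------------------
# Replicate studies


@dataclass(frozen=True)
class StudyConfig:
    """Conditions for a replicate study.

    ``engine``: 'mosaic' (self-contained PAC generator), 'coalescent'
    (msprime, constant size 1) or 'coalescent-expansion' (msprime with
    the synthetic two-epoch expansion).  Rates are population-scaled per
    bp for the coalescent engines; the mosaic engine uses the LS
    generative probabilities directly.  Replicate ``i`` uses seed
    ``seed + i``.
    """

    engine: str = "coalescent"
    N: int = 100
    L: int = 400
    sequence_length: float = 1e6
    mutation_rate: float = 1e-4
    recombination_rate: float = 1e-4
    p_theta: float = 5e-3
    p_rho: float = 5e-4
    maf_threshold: float = 0.05
    seed: int = 0

    def reference_c(self) -> float:
        """Penalty ratio implied by the population-scaled rates
        (theta = 4 Ne mu with Ne = E[T_MRCA]/2, as in the evaluation
        protocol)."""
        if self.engine == "mosaic":
            return beta_from_p(self.p_rho, self.N) / alpha_from_p(self.p_theta)
        if self.engine == "coalescent":
            et2 = 1.0
        elif self.engine == "coalescent-expansion":
            et2 = expected_pairwise_tmrca(expansion_demography())
        else:
            raise ValueError(f"unknown engine {self.engine!r}")
        theta = 2.0 * et2 * self.mutation_rate
        rho = 2.0 * et2 * self.recombination_rate
        return penalty_ratio(theta, rho, self.N)

    def demography(self):
        if self.engine == "coalescent-expansion":
            return expansion_demography()
        return None


def _simulate_haplotypes(config: StudyConfig, n_haps: int, seed: int) -> AlleleMatrix:
    if config.engine == "mosaic":
        gc = GenerativeConfig(
            N=n_haps, L=config.L, p_theta=config.p_theta, p_rho=config.p_rho,
            seed=seed, maf_threshold=config.maf_threshold,
        )
        return generate_panel(gc)
    return coalescent_panel(
        n_haplotypes=n_haps,
        sequence_length=config.sequence_length,
        mutation_rate=config.mutation_rate,
        recombination_rate=config.recombination_rate,
        seed=seed,
        demography=config.demography(),
    )


def run_imputation_replicates(config: StudyConfig, replicates: int) -> pd.DataFrame:
    """Haploid imputation study: mask rare sites, decode the surface on
    the retained sites, impute the masked sites from each region's
    representative path, and locate the minimal-error beta interval.

    Returns one row per (replicate, loss kind); failed replicates are
    recorded with ``ok=False`` rather than raising.
    """
    rows = []
    ref_c = Fraction(config.reference_c())
    for rep in range(replicates):
        seed = config.seed + rep
        try:
            rows.extend(_imputation_once(config, seed, rep, ref_c))
        except Exception as exc:  # pragma: no cover - defensive
            rows.append({"replicate": rep, "ok": False, "error": str(exc)})
    return pd.DataFrame(rows)


def _imputation_once(config: StudyConfig, seed: int, rep: int, ref_c: Fraction):
    if config.engine == "mosaic":
        panel = _simulate_haplotypes(config, config.N, seed)
        focal, _truth_path = sample_focal(panel, config.p_theta, config.p_rho, seed + 10_000_019)
        full = np.concatenate([focal.alleles[:, None], panel.alleles], axis=1)
    else:
        sim = _simulate_haplotypes(config, config.N + 1, seed)
        full = sim.alleles
        focal = Haplotype(full[:, 0])
        panel = AlleleMatrix(full[:, 1:])
    retained, masked = mask_by_maf(full, config.maf_threshold)
    if retained.size == 0 or masked.size == 0:
        raise RuntimeError("degenerate MAF split")
    H_ret = AlleleMatrix(panel.alleles[retained])
    surface = partition_haploid(Haplotype(focal.alleles[retained]), H_ret)
    truth_masked = focal.alleles[masked]
    w = maf_weights(full, masked)

    def hamming(path):
        imp = impute_from_path(path, retained, masked, panel)
        return imputation_loss(truth_masked, imp)

    def weighted(path):
        imp = impute_from_path(path, retained, masked, panel)
        return imputation_loss(truth_masked, imp, weights=w)

    out = []
    for kind, fn in (("hamming", hamming), ("maf_weighted", weighted)):
        curve = loss_curve(surface, fn, kind)
        opt = optimal_interval(curve, ref_c)
        out.append(
            {
                "replicate": rep,
                "ok": True,
                "loss_kind": kind,
                "n_regions": len(surface.vertices),
                "n_retained": int(retained.size),
                "n_masked": int(masked.size),
                "min_loss": opt.loss,
                "opt_lo": float(opt.lo),
                "opt_hi": np.inf if opt.hi is None else float(opt.hi),
                "multimodal": opt.multimodal,
                "contains_reference": opt.contains_reference_beta,
            }
        )
    return out


def run_phasing_replicates(config: StudyConfig, replicates: int) -> pd.DataFrame:
    """Diploid phasing study: decode the pair surface of an unphased
    diplotype built from two held-out haplotypes, phase each region's
    representative pair, and locate the minimal-switch-error interval."""
    rows = []
    ref_c = Fraction(config.reference_c())
    for rep in range(replicates):
        seed = config.seed + rep
        try:
            sim = _simulate_haplotypes(config, config.N + 2, seed)
            full = sim.alleles
            h1, h2 = Haplotype(full[:, 0]), Haplotype(full[:, 1])
            panel = AlleleMatrix(full[:, 2:])
            g = GenotypeSequence.from_haplotypes(h1, h2)
            surface = partition_diploid(g, panel)

            def sw(pair):
                est = phase_from_pair(pair, panel)
                se = switch_error((h1, h2), est)
                return np.inf if se.rate is None else se.count

            curve = loss_curve(surface, sw, "switch_error")
            opt = optimal_interval(curve, ref_c)
            rows.append(
                {
                    "replicate": rep,
                    "ok": True,
                    "loss_kind": "switch_error",
                    "n_regions": len(surface.vertices),
                    "n_sites": panel.n_sites,
                    "min_loss": opt.loss,
                    "opt_lo": float(opt.lo),
                    "opt_hi": np.inf if opt.hi is None else float(opt.hi),
                    "multimodal": opt.multimodal,
                    "contains_reference": opt.contains_reference_beta,
                }
            )
        except Exception as exc:  # pragma: no cover - defensive
            rows.append({"replicate": rep, "ok": False, "error": str(exc)})
    return pd.DataFrame(rows)


def summarize_fraction_optimal(df: pd.DataFrame) -> pd.Series:
    """Fraction of successful replicates whose reference beta fell in the
    optimal interval, per loss kind."""
    good = df[df["ok"]]
    return good.groupby("loss_kind")["contains_reference"].mean()
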