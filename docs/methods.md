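# Methods

## Model and normalization

The Li–Stephens (LS) model is a hidden Markov model over copying paths
π ∈ [N]^L. Between adjacent sites the path switches templates with a
constant probability (a switch redraws the template uniformly among all
N, so staying put has probability 1 − N·p_ρ); at each site the focal
allele copies the template allele except with error probability p_θ
(for nucleotides, the error is uniform over the three alternatives, so
correct copying has probability 1 − 3·p_θ). Up to a path-independent
constant the negative log-likelihood is α·m(π) + β·k(π) with

    α = −log[p_θ / (1 − 3 p_θ)],    β = −log[p_ρ / (1 − N p_ρ)].

We require min{α, β} > 0, i.e. p_θ < 1/4 and p_ρ < 1/(N+1); this always
holds under the rate maps used here, p_θ = (1 − e^{−θ/N})/3 and
p_ρ = (1 − e^{−ρ/N})/N (the original p_θ = θ̃/[2(N + θ̃)] map is also
provided). Only the ratio c = β/α affects the argmin, so the library
normalizes α = 1 and works with the single penalty β = c. The
`equivalence_curve` helper materializes the one-parameter family of
(p_θ, p_ρ) pairs sharing a given c.

Constant inter-site switch probability is a modeling assumption: there
is no per-site recombination map, and no posterior/forward–backward
variant is provided (the surface construction is specific to the
Viterbi decoding).

## The surface algorithm

Let J_ℓ(r) be the minimal mismatch count among length-ℓ paths with
exactly r switches. The optimal cost at penalty β is
V_ℓ(β) = min_r J_ℓ(r) + β·r, a concave piecewise-linear function of β
whose pieces correspond to vertices of the lower convex hull of
{(r, J_ℓ(r))}; the breakpoints are the exact rational slopes

    β_i = [J(r_i) − J(r_{i+1})] / (r_{i+1} − r_i).

Because β > 0, only the *lower-left* part of the hull matters: the chain
with strictly increasing r, strictly decreasing m, and strictly
increasing (negative) slopes, ending at the leftmost minimal-m point.
Points on slope-≥ 0 segments (including the truncated-epigraph boundary
points at m = ℓ) can never minimize m + β·r and are discarded.

The one-pass recurrence maintains, at each site, a hull chain F⁽ⁿ⁾ per
template n (costs of paths ending at n) and the global chain G (their
merge). Extending to the next site with mismatch indicator d(n):

    candidates(n) = {(r, m + d(n)) : (r, m) ∈ F⁽ⁿ⁾}        (no switch)
                  ∪ {(r + 1, m + d(n)) : (r, m) ∈ G}       (switch onto n)

and the new F⁽ⁿ⁾ is the lower-left hull of the candidates. Keeping only
hull vertices is lossless: an optimal extension's parent must itself be
a (locally or globally) active vertex. Candidates that would encode a
fictitious switch (a G vertex whose path already ends at n) are always
dominated by the corresponding no-switch candidate at equal m and
smaller r, so they can never survive the hull; this is also exercised by
the enumeration tests. Hull construction is Andrew's monotone chain on
r-sorted points with exact integer cross-products.

The diploid variant tracks hull chains per unordered template pair
(n₁ ≤ n₂), per single template ("partially active": best over all pairs
containing n, feeding one-switch extensions), and globally (feeding
two-switch extensions). Candidate order is: both-stay, switch-other-
than-n₁, switch-other-than-n₂, both-switch, mirroring the four parent
cases. The state space over unordered pairs halves the work and makes
the output invariant to the allele order inside genotypes. Per-site work
is Θ(N²) pair updates.

Every surviving vertex carries a backpointer (parent vertex, continuing
template(s), switch type); one representative optimal path (or pair) per
final vertex is reconstructed by walking these pointers, and tests
verify the reconstruction reproduces the vertex's (r, m) exactly.

### Tie-breaking and conventions

* Ties between candidates with identical (r, m) prefer fewer new
  switches, then the lowest template index — representative paths are
  deterministic and reproducible. Which optimal path is chosen inside a
  region is otherwise arbitrary, and downstream losses are defined with
  respect to this deterministic representative; realized loss curves can
  therefore differ from other implementations in regions with many
  co-optimal paths.
* Regions are half-open: vertex i is optimal on [β_i, β_{i−1}); exactly
  at a breakpoint both neighbours are optimal, the smaller-r vertex is
  reported and the tie flagged. Float β queries are converted to exact
  rationals, so region lookup involves no floating-point comparisons.
* Diploid site mismatch uses literal set semantics
  |{g₁,g₂} △ {copied₁, copied₂}|. For biallelic data this equals the
  absolute dosage difference (enumerated exhaustively in the tests).
  For larger alphabets set-vs-multiset semantics is genuinely ambiguous
  (e.g. g = {a,a} against templates {c,c} scores 2, not 4); the set
  reading is used throughout.
* Indices are 0-based half-open internally.

## Independent references

The `oracle` module exists only for validation: exhaustive enumeration
of all N^L paths (or all path pairs), fixed-β Viterbi with exact
arithmetic (β = p/q handled by minimizing the integer q·m + p·k), and
the direct J-table dynamic program over (site, switches, template). The
test suite requires exact equality between the surface and these
references — vertex sets, costs at sampled rational β, and breakpoint
kink locations — never approximate agreement. (The pointwise-minimum
piecewise-linear recursion over β is intentionally not a production
path; it is slow for large N.)

## Synthetic data

The self-contained panel generator is PAC-style ("mosaic"): a founder
haplotype carries sparse derived alleles, and each subsequent haplotype
is an LS-style copy of the previously generated ones (switch probability
N·p_ρ per transition, flip probability p_θ per site), keeping only
segregating sites. This produces LD-block structure and a decreasing
site-frequency spectrum, which is what the surface algorithms are
sensitive to. It is not a coalescent: it has no underlying genealogy,
no physical coordinates, and its SFS only qualitatively matches the
neutral 1/i shape. Passing tests on mosaic data therefore demonstrate
algorithmic correctness and sensible end-to-end behavior, not calibrated
population-genetic realism; the replicate studies use msprime panels
instead.

The focal sampler draws the latent path from the stationary switch
process and miscopies with probability p_θ (biallelic alleles flip —
the three-alternatives rule degenerates for two alleles). Monte-Carlo
tests check the expected mismatch count L·p_θ and expected switch count
(L−1)·N·p_ρ·(1−1/N), since a redraw landing on the same template is not
a switch.

MAF masking computes minor allele frequency over the full simulated
sample *including* the focal chromosome(s) — the filter is applied
before the focal/panel split — and retains sites with MAF ≥ 0.05 by
default. The analytic companion `expected_maf_retention` gives the
neutral-SFS probability that a segregating site passes the filter
(≈ 39.2% at n = 1001, threshold 0.05).

## Replicate studies

Imputation (haploid): simulate n = N+1 haplotypes, take the first as
truth, mask rare sites, decode the surface on the retained markers, and
impute each masked site by copying from the template used at the nearest
retained marker (index distance, ties to the left flank, leading sites
use the first marker). Losses: Hamming, and inverse-variance weights
1/[MAF(1−MAF)] with MAF taken from the full pre-masking sample (masked
sites have no panel-only frequency by construction). For each loss the
maximal union of contiguous minimal-loss regions is located; if minima
are non-contiguous all runs are reported and the primary run is the one
with the smallest β lower bound. The study records whether the
*reference* penalty falls in the primary optimal interval, where the
reference is c = β(ρ₀)/α(θ₀) with population-scaled rates
θ₀ = 4·Nₑ·μ, ρ₀ = 4·Nₑ·r and Nₑ = E[T_MRCA]/2 for a pair of
chromosomes under the simulated demography.

Phasing (diploid): simulate N+2 haplotypes, combine the first two into
an unphased diplotype, decode the pair surface against the rest, phase
each region's representative pair (emitting copied template alleles,
also at mismatch sites), and score switch errors. Switch error follows
the vcftools --diff-switch-error convention: only sites heterozygous in
both truth and estimate with matching allele sets are compared, the
count is the number of adjacent orientation flips, the rate divides by
comparable sites minus one (0 comparable sites → undefined; 1 → rate 0).
Exact parity with any particular vcftools build is not asserted.

Study conditions (chosen once as desk-scale analogues of the full
protocol, which uses 1000 replicates of ~100 Mb panels with 1000
templates): panels of N = 100 templates over 1 Mb at scaled rates
θ = ρ = 10⁻⁴ per bp for imputation (a few hundred retained markers per
replicate; 15–40 replicates), and N = 40 over 0.25 Mb for phasing. Two
demographies are used: constant size, and a synthetic single-population
growth model (explosive recent expansion over a moderate middle epoch
and a smaller ancestral size — the qualitative shape of African human
demographic history, *not* a calibrated published model; stdpopsim-style
calibrated demographies can be substituted through the
`coalescent_panel(demography=...)` hook). At these sizes the constant-
size study reproduces the expected contrast (the reference penalty is
optimal for Hamming loss clearly more often than for the rare-variant-
weighted loss). The growth study does not reproduce the full-scale
finding that its Hamming fraction exceeds the constant-size one: the
growth demography yields ~2.4× more retained markers per Mb, hence more
surface regions and narrower optimal intervals, which mechanically
lowers containment fractions at this scale. The corresponding acceptance
test documents this as a failing expectation rather than weakening the
check.

## Known limitations

* Pure-Python frontier updates: comfortable to N ≈ a few hundred
  (haploid) / N ≈ 100 (diploid); large-panel scaling is out of scope.
* One representative path per region, not an enumeration of all
  co-optimal paths.
* Constant inter-site switch probability; no recombination-map variant.
* The number of hull vertices grows slowly with L and N but is not
  characterized analytically here.
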