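# lssurface

**The exact solution surface of the Li–Stephens haplotype copying model.**

The Li–Stephens (LS) model explains a "focal" chromosome of *L* linked
markers as a mosaic of *N* template chromosomes: a latent copying path
π ∈ [N]^L picks a template at every site, switching templates with a
recombination-driven probability and miscopying alleles with a
mutation-driven probability. Up to an additive constant, the negative
log-likelihood of a path is

    α(θ)·m(π) + β(ρ)·k(π)

where m(π) counts allele mismatches, k(π) counts template switches, and
α, β are decreasing functions of the mutation rate θ and recombination
rate ρ. Only the ratio c = β/α matters for which path is optimal, so
after normalizing α = 1 the entire (θ, ρ) plane collapses onto a single
switch penalty β.

Practitioners usually pick one β (from population-scaled rates) and run
Viterbi once. `lssurface` instead computes **every** Viterbi decoding at
once: a single pass over the data returns the finite set of optimal
(k, m) cost profiles together with the exact rational breakpoints
β₁ > β₂ > ⋯ partitioning (0, ∞) into constant-decoding regions. The key
observations are that the minimal mismatch count J(r) among paths with
exactly r switches determines the optimum through
V(β) = min_r J(r) + β·r, that only vertices of the lower convex hull of
{(r, J(r))} are ever optimal, and that this hull can be propagated
site-by-site using per-template ("locally active") hulls. Because
everything lives on the integer lattice, the computation is exact —
identical on every platform, immune to floating-point rounding. A
diploid variant decodes pairs of copying paths for unphased genotypes
(useful for phasing), scaling as O(N²) per site.

Intended for statistical geneticists studying how the penalty (i.e. the
assumed recombination/mutation balance) affects LS-based imputation and
phasing, and for method developers who need exact regularization-path
ground truth for the LS Viterbi problem.

## Worked example

`examples/01_haploid_surface.py` simulates a 200-site, 30-template
mosaic panel, samples a focal haplotype from the LS generative process
(the hidden truth used 21 switches and 4 copying errors), and prints the
complete surface:

```
6 distinct optimal decodings as beta sweeps (0, inf):
           beta interval   r (switches)   m (mismatches)
[    5.000,       inf)              0               28
[    4.000,     5.000)              1               23
[    2.000,     4.000)              3               15
[    1.500,     2.000)              6                9
[    1.000,     1.500)              8                6
[    0.000,     1.000)             14                0

at beta=1.0: optimal decoding uses 8 switches and 6 mismatches (cost 14.0)
```

Reading the table: with a high switch penalty (β > 5) LS copies one
template in its entirety, paying 28 mismatches; as β falls, the decoder
buys recombinations to remove mismatches, until below β = 1 a zero-
mismatch mosaic with 14 switches is optimal. The breakpoints (5, 4, 2,
3/2, 1) are exact rationals — between them the decoding never changes.
Each region carries a representative optimal path whose (k, m) equals
the region's vertex exactly.

The other examples show diploid phasing with per-region switch error
(`02`), the one-dimensional manifold of equivalent (p_θ, p_ρ) settings
(`03`), and a miniature imputation study over the surface (`04`).

A thin CLI mirrors the library: `lssurface haploid|diploid` decode a
plain matrix or phased VCF and emit the surface as JSON;
`lssurface simulate` writes synthetic panels; `lssurface impute-study` /
`phase-study` run the replicate experiments.

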