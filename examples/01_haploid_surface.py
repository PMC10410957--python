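"""Compute every haploid LS decoding of a focal haplotype at once.

Builds a small mosaic panel, samples a focal haplotype from the LS
generative process, and prints the whole solution surface: one (switches,
mismatches) vertex per constant-decoding region of the penalty axis,
with the exact rational breakpoints between regions.
"""

import numpy as np

from lssurface import GenerativeConfig, generate_panel, partition_haploid, sample_focal
from lssurface.model import mismatch_count, switch_count

cfg = GenerativeConfig(N=30, L=200, p_theta=0.02, p_rho=0.004, seed=7)
H = generate_panel(cfg)
h, truth = sample_focal(H, cfg.p_theta, cfg.p_rho, seed=8)
print(f"panel: {H.n_sites} sites x {H.n_templates} templates")
print(f"latent truth path: {switch_count(truth)} switches, "
      f"{mismatch_count(truth, h, H)} copying errors\n")

surface = partition_haploid(h, H)
print(f"{len(surface.vertices)} distinct optimal decodings as beta sweeps (0, inf):")
print(f"{'beta interval':>24}   r (switches)   m (mismatches)")
for (lo, hi), v in zip(surface.regions, surface.vertices):
    hi_s = "inf" if hi is None else f"{float(hi):.3f}"
    print(f"[{float(lo):>9.3f}, {hi_s:>9})   {v.r:>12}   {v.m:>14}")

# Each region's representative path attains exactly that vertex's cost.
beta = 1.0
idx, _ = surface.optimal_vertex(beta)
path = surface.representative_paths[idx]
print(f"\nat beta={beta}: optimal decoding uses {switch_count(path)} switches "
      f"and {mismatch_count(path, h, H)} mismatches (cost {float(surface.cost_at(beta)):.1f})")
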