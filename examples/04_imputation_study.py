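"""A miniature imputation replicate study.

Per replicate: simulate a coalescent panel plus focal haplotype, mask
every site with minor allele frequency below 0.05, decode the surface on
the retained markers, impute each masked site from the nearest flanking
marker's copied template, and find the beta interval minimizing the
imputation error.  The summary reports how often the population-scaled
reference penalty landed inside that optimal interval.
"""

from lssurface import StudyConfig, run_imputation_replicates
from lssurface.experiments import summarize_fraction_optimal
import numpy as np

cfg = StudyConfig(engine="coalescent", N=60, sequence_length=5e5, seed=1)
print(f"reference penalty ratio c = {cfg.reference_c():.4f} "
      f"(log(1+c) = {np.log1p(cfg.reference_c()):.3f})")
df = run_imputation_replicates(cfg, 6)
cols = ["replicate", "loss_kind", "n_retained", "n_masked", "n_regions",
        "min_loss", "opt_lo", "opt_hi", "contains_reference"]
print(df[df["ok"]][cols].to_string(index=False))
print("\nfraction of replicates where the reference penalty was optimal:")
print(summarize_fraction_optimal(df).to_string())
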