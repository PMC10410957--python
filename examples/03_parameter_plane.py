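"""The (theta, rho) plane collapses onto one penalty ratio.

The LS decoding depends on the mutation and recombination rates only
through c = beta(rho)/alpha(theta).  This script prints a curve of
(p_theta, p_rho) pairs that all share the same c — every point on it
gives the identical decoding — and verifies the ratio numerically.
"""

from lssurface.model import alpha_from_p, beta_from_p, equivalence_curve, penalty_ratio

N = 1000
theta = rho = 1e-4  # population-scaled rates per marker
c = penalty_ratio(theta, rho, N)
print(f"panel size N={N}, theta=rho={theta:g}  ->  penalty ratio c = {c:.4f}")
print("equivalent parameterizations (identical LS output):")
print(f"{'p_theta':>10} {'p_rho':>14} {'beta/alpha':>12}")
for pt, pr in equivalence_curve(c, [0.001, 0.01, 0.05, 0.1, 0.2], N):
    print(f"{pt:>10.4g} {pr:>14.4g} {beta_from_p(pr, N) / alpha_from_p(pt):>12.6f}")
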