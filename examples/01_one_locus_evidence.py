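"""One locus, closed form: posterior mean, CDF jump, and the measure of evidence.

Builds the sufficient statistics of a single standardized SNP with a clear
effect, evaluates the spike-plus-Laplace posterior in closed form and prints
the quantities a practitioner reads: the shrunken effect estimate, the
posterior probability of 'exactly zero', and the HPD-tangent-to-zero
credibility kappa with its decision MOE = 1 - kappa.
"""

import numpy as np

from spikewgr import (
    HpdGridSpec,
    LocusSufficientStats,
    PriorSpec,
    bayes_factor,
    hpd_credibility,
    posterior_cdf,
    posterior_mean,
)

rng = np.random.default_rng(7)
n = 500
x = rng.standard_normal(n)  # standardized genotype column
g_true = 0.25
y = g_true * x + rng.normal(0.0, 1.0, n)

stats = LocusSufficientStats.from_xy(x, y, sigma_e2=1.0)
prior = PriorSpec(gamma=0.05, lam=10.0)
post = posterior_mean(stats, prior)

eps = 1e-12
spike_mass = posterior_cdf(eps, post) - posterior_cdf(-eps, post)
half = 10 * (abs(post.ghat) + np.sqrt(post.sigma2))
ev = hpd_credibility(post, HpdGridSpec(-half, half))
log_b = bayes_factor(post.ghat, stats.xty, stats.xtx, stats.sigma_e2)

print(f"least-squares estimate Y        : {stats.Y:+.4f}")
print(f"posterior mean ghat             : {post.ghat:+.4f}   (shrunken toward 0)")
print(f"posterior P(g = 0 | y)          : {spike_mass:.4f}   (mass of the spike)")
print(f"HPD credibility kappa           : {ev.kappa:.4f}   borders ({ev.t1:+.4f}, {ev.t2:+.4f})")
print(f"measure of evidence MOE         : {ev.moe:.4f}   (significant at alpha if MOE <= alpha)")
print(f"Bayes factor B                  : {np.exp(log_b):.2f}    (substantial if B > 3)")
print()
print("With a true effect of 0.25 at n=500 the evidence is overwhelming:")
print("MOE is near 0 and B is far above 3; both rules flag the locus.")
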