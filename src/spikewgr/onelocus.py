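"""Closed-form one-locus posterior under a spike-plus-Laplace prior.

The one-locus model is y = x g + e with e ~ N(0, I sigma_e^2) and prior

    p(g | gamma) = gamma * (lambda/2) exp(-lambda |g|) + (1 - gamma) delta_0,

i.e. the effect is zero with probability 1 - gamma and Laplace(lambda)
distributed otherwise.  Everything needed downstream is available in closed
form through the sufficient statistics

    Y = (x'x)^{-1} x'y,     sigma^2 = (x'x)^{-1} sigma_e^2.

This module provides the posterior mean, the analytic posterior CDF (with
its jump of height f2(0)/p(y) at zero), the continuous posterior density,
the credibility kappa of the highest-posterior-density interval tangent to
zero (the basis of the measure of evidence MOE = 1 - kappa), and the
marginal Bayes factor.

All mixture weights are handled on the log scale: the textbook products
such as exp(-lambda Y) * (1 - Phi(0; Y - lambda sigma^2, sigma^2)) overflow
for routine whole-genome inputs, so T1, T2, T3 and the f-functions are
combined by log-sum-exp with normal tail probabilities evaluated through
``scipy.special.log_ndtr``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, logsumexp

_LOG_2PI = math.log(2.0 * math.pi)

__all__ = [
    "PriorSpec",
    "LocusSufficientStats",
    "LocusPosterior",
    "EvidenceResult",
    "HpdGridSpec",
    "truncated_normal_mean",
    "posterior_mean",
    "posterior_cdf",
    "continuous_density",
    "hpd_credibility",
    "bayes_factor",
    "posterior_mean_scalar",
]


@dataclass(frozen=True)
class PriorSpec:
    """Mixing probability gamma = P(g != 0) and Laplace rate lambda."""

    gamma: float
    lam: float

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must lie in (0, 1]")
        if not (self.lam > 0.0):
            raise ValueError("lambda must be positive")


@dataclass(frozen=True)
class LocusSufficientStats:
    """GLS statistics of the one-locus model: Y = x'y / x'x, sigma2 = sigma_e2 / x'x."""

    xtx: float
    xty: float
    sigma_e2: float

    def __post_init__(self) -> None:
        if not (self.xtx > 0.0 and self.sigma_e2 > 0.0):
            raise ValueError("x'x and sigma_e2 must be positive")
        if not (np.isfinite(self.xtx) and np.isfinite(self.xty) and np.isfinite(self.sigma_e2)):
            raise ValueError("non-finite sufficient statistics")

    @property
    def Y(self) -> float:
        return self.xty / self.xtx

    @property
    def sigma2(self) -> float:
        return self.sigma_e2 / self.xtx

    @classmethod
    def from_xy(cls, x: np.ndarray, y: np.ndarray, sigma_e2: float) -> "LocusSufficientStats":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return cls(xtx=float(x @ x), xty=float(x @ y), sigma_e2=sigma_e2)


@dataclass(frozen=True)
class LocusPosterior:
    """Log-scale mixture weights and the posterior mean of one effect.

    T1 weighs the positive Laplace branch, T2 the negative branch and T3 the
    spike at zero; log_py is log p(y) up to the constant common to all three
    branches.
    """

    Y: float
    sigma2: float
    prior: PriorSpec
    log_T1: float
    log_T2: float
    log_T3: float
    ghat: float

    @property
    def log_laplace_const(self) -> float:
        """log(gamma * lambda / 2) + lambda^2 sigma^2 / 2, the factor shared by f1 and f3."""
        p = self.prior
        return math.log(p.gamma * p.lam / 2.0) + 0.5 * p.lam**2 * self.sigma2

    @property
    def log_py(self) -> float:
        return self.log_laplace_const + logsumexp([self.log_T1, self.log_T2, self.log_T3])


@dataclass(frozen=True)
class EvidenceResult:
    """HPD-tangent-to-zero credibility kappa, MOE = 1 - kappa, borders, Bayes factor."""

    kappa: float
    moe: float
    t1: float
    t2: float
    log_bayes_factor: float = float("nan")

    @property
    def bayes_factor(self) -> float:
        return math.exp(self.log_bayes_factor)


@dataclass(frozen=True)
class HpdGridSpec:
    """Grid-search parameters for the HPD border: interval [mL, mU], fixed step count."""

    m_lower: float
    m_upper: float
    steps: int = 2000
    exact: bool = False

    def __post_init__(self) -> None:
        if not self.exact and not (self.m_lower < self.m_upper):
            raise ValueError("grid requires m_lower < m_upper")


def _log_phi(x: float, mu: float, sigma2: float) -> float:
    return -0.5 * (_LOG_2PI + math.log(sigma2)) - 0.5 * (x - mu) ** 2 / sigma2


def truncated_normal_mean(side: str, mu: float, sigma2: float) -> float:
    """Mean of N(mu, sigma2) truncated at zero.

    ``side='upper'`` conditions on g > 0, ``side='lower'`` on g < 0.  The
    Mills ratio phi/Phi is evaluated as exp(logpdf - logcdf) so that deep
    tails (|mu|/sigma large) stay finite and accurate.
    """
    if sigma2 <= 0.0:
        raise ValueError("sigma2 must be positive")
    if side not in ("upper", "lower"):
        raise ValueError("side must be 'upper' or 'lower'")
    return float(_trunc_mean_batch(side == "upper", mu, math.sqrt(sigma2)))


def _log_T123(Y, sigma2, gamma, lam):
    """Vectorized log T1, T2, T3 given arrays/scalars Y, sigma2."""
    sigma = np.sqrt(sigma2)
    y_minus = Y - lam * sigma2
    y_plus = Y + lam * sigma2
    log_T1 = -lam * Y + log_ndtr(y_minus / sigma)
    log_T2 = lam * Y + log_ndtr(-y_plus / sigma)
    if gamma >= 1.0:
        log_T3 = np.full_like(np.asarray(log_T1, dtype=float), -np.inf)
    else:
        log_T3 = (
            math.log(2.0 * (1.0 - gamma) / (gamma * lam))
            - 0.5 * lam**2 * sigma2
            - 0.5 * (_LOG_2PI + np.log(sigma2))
            - 0.5 * Y**2 / sigma2
        )
    return log_T1, log_T2, log_T3


def _deep_tail_trunc_mean(a, sigma):
    """mu + sigma*phi(a)/Phi(a) for a <= -25 (equivalently the lower-side
    mirror), via the asymptotic Mills-ratio series: the direct difference
    cancels catastrophically when |mu| >> result."""
    a2 = a * a
    t = (-1.0 + (3.0 - (15.0 - 105.0 / a2) / a2) / a2) / a
    s = 1.0 + (-1.0 + (3.0 + (-15.0 + 105.0 / a2) / a2) / a2) / a2
    return sigma * t / s


def _trunc_mean_batch(side_upper: bool, mu, sigma):
    a = np.asarray(mu / sigma, dtype=float)
    deep = 25.0
    with np.errstate(over="ignore", invalid="ignore"):
        log_mills = -0.5 * (_LOG_2PI + a * a)
        if side_upper:
            safe_a = np.maximum(a, -deep)
            direct = mu + sigma * np.exp(log_mills - log_ndtr(safe_a))
            out = np.where(a <= -deep, _deep_tail_trunc_mean(np.minimum(a, -deep), sigma), direct)
        else:
            safe_a = np.minimum(a, deep)
            direct = mu - sigma * np.exp(log_mills - log_ndtr(-safe_a))
            out = np.where(a >= deep, _deep_tail_trunc_mean(-np.maximum(a, deep), sigma) * -1.0, direct)
    return out if out.ndim else float(out)


def posterior_mean_scalar(Y: float, sigma2: float, gamma: float, lam: float) -> float:
    """Fast scalar posterior expectation E(g | y); the solver's inner kernel."""
    log_T1, log_T2, log_T3 = _log_T123(Y, sigma2, gamma, lam)
    log_Z = logsumexp([log_T1, log_T2, log_T3])
    sigma = math.sqrt(sigma2)
    theta_u = _trunc_mean_batch(True, Y - lam * sigma2, sigma)
    theta_l = _trunc_mean_batch(False, Y + lam * sigma2, sigma)
    return float(math.exp(log_T1 - log_Z) * theta_u + math.exp(log_T2 - log_Z) * theta_l)


def posterior_mean(stats: LocusSufficientStats, prior: PriorSpec) -> LocusPosterior:
    """Posterior expectation ghat = (T1 Theta_U + T2 Theta_L) / (T1 + T2 + T3)."""
    Y, sigma2 = stats.Y, stats.sigma2
    log_T1, log_T2, log_T3 = _log_T123(Y, sigma2, prior.gamma, prior.lam)
    log_Z = logsumexp([log_T1, log_T2, log_T3])
    sigma = math.sqrt(sigma2)
    ghat = math.exp(log_T1 - log_Z) * _trunc_mean_batch(True, Y - prior.lam * sigma2, sigma) + math.exp(
        log_T2 - log_Z
    ) * _trunc_mean_batch(False, Y + prior.lam * sigma2, sigma)
    return LocusPosterior(
        Y=Y,
        sigma2=sigma2,
        prior=prior,
        log_T1=float(log_T1),
        log_T2=float(log_T2),
        log_T3=float(log_T3),
        ghat=float(ghat),
    )


def _log_ndtr_diff(hi: np.ndarray, lo: np.ndarray):
    """log( Phi(hi) - Phi(lo) ) for hi >= lo, stable in both tails."""
    hi = np.asarray(hi, dtype=float)
    lo = np.asarray(lo, dtype=float)
    # use the CDF on the left tail, the survival function on the right
    use_sf = lo > 0.0
    a = np.where(use_sf, log_ndtr(-lo), log_ndtr(hi))
    b = np.where(use_sf, log_ndtr(-hi), log_ndtr(lo))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = a + np.log1p(-np.minimum(np.exp(b - a), 1.0))
    return np.where(hi <= lo, -np.inf, out)


def _log_spike(post: LocusPosterior) -> float:
    """log[(1-gamma) phi(0; Y, sigma^2)]; -inf when gamma = 1."""
    return post.log_laplace_const + post.log_T3


def posterior_cdf(t: float, post: LocusPosterior) -> float:
    """Analytic posterior probability P(g < t | y).

    Piecewise: the Laplace branch f1 on (-inf, 0), the spike f2(0) delta_0,
    and f3 on (0, inf), all normalized by p(y).  The CDF jumps by
    f2(0)/p(y) at t = 0; the value returned at exactly t = 0 is the
    left limit (the spike mass sits at zero itself).
    """
    prior, Y, sigma2 = post.prior, post.Y, post.sigma2
    sigma = math.sqrt(sigma2)
    lam = prior.lam
    pieces = []
    # integral of f1 over (-inf, min(t, 0))
    u = min(t, 0.0)
    pieces.append(post.log_laplace_const + lam * Y + log_ndtr((u - (Y + lam * sigma2)) / sigma))
    if t > 0.0:
        pieces.append(_log_spike(post))
        lo = (0.0 - (Y - lam * sigma2)) / sigma
        hi = (t - (Y - lam * sigma2)) / sigma
        pieces.append(post.log_laplace_const - lam * Y + float(_log_ndtr_diff(hi, lo)))
    return float(np.exp(logsumexp(pieces) - post.log_py))


def continuous_density(g: float, post: LocusPosterior) -> float:
    """Continuous part of the posterior density, f1(g)/p(y) or f3(g)/p(y).

    f1 and f3 share the one-sided limit at zero, so the continuous density
    is well defined (and continuous) at g = 0 even though the full
    posterior carries the spike there.
    """
    prior, Y, sigma2 = post.prior, post.Y, post.sigma2
    lam = prior.lam
    if g < 0.0:
        log_f = post.log_laplace_const + lam * Y + _log_phi(g, Y + lam * sigma2, sigma2)
    elif g > 0.0:
        log_f = post.log_laplace_const - lam * Y + _log_phi(g, Y - lam * sigma2, sigma2)
    else:
        log_f = post.log_laplace_const - lam * Y + _log_phi(0.0, Y - lam * sigma2, sigma2)
    return float(math.exp(log_f - post.log_py))


def _kappa_from_border(post: LocusPosterior, border: float) -> float:
    """kappa = posterior mass of the open interval between 0 and the border."""
    prior, Y, sigma2 = post.prior, post.Y, post.sigma2
    sigma = math.sqrt(sigma2)
    lam = prior.lam
    if border > 0.0:
        lo = (0.0 - (Y - lam * sigma2)) / sigma
        hi = (border - (Y - lam * sigma2)) / sigma
        log_mass = post.log_laplace_const - lam * Y + float(_log_ndtr_diff(hi, lo))
    elif border < 0.0:
        lo = (border - (Y + lam * sigma2)) / sigma
        hi = (0.0 - (Y + lam * sigma2)) / sigma
        log_mass = post.log_laplace_const + lam * Y + float(_log_ndtr_diff(hi, lo))
    else:
        return 0.0
    return float(np.exp(log_mass - post.log_py))


def hpd_credibility(post: LocusPosterior, grid: HpdGridSpec) -> EvidenceResult:
    """Credibility kappa of the HPD interval tangent to zero.

    For ghat > 0 the border is the largest g > 0 whose continuous posterior
    density still reaches the density at zero, located by a grid search over
    [m_lower, m_upper] with (m_upper - m_lower)/steps spacing; mirror image
    for ghat < 0.  ``grid.exact`` replaces the search by the closed-form
    border 2(Y -/+ lambda sigma^2) of the Gaussian branch.  ghat = 0 returns
    kappa = 0 (MOE = 1, never significant) since the defining interval is
    empty.
    """
    ghat = post.ghat
    if ghat == 0.0:
        return EvidenceResult(kappa=0.0, moe=1.0, t1=0.0, t2=0.0)
    lam, Y, sigma2 = post.prior.lam, post.Y, post.sigma2
    if grid.exact:
        border = 2.0 * (Y - lam * sigma2) if ghat > 0 else 2.0 * (Y + lam * sigma2)
        border = max(border, 0.0) if ghat > 0 else min(border, 0.0)
    else:
        points = np.linspace(grid.m_lower, grid.m_upper, grid.steps + 1)
        dens0 = continuous_density(0.0, post)
        if ghat > 0:
            cand = points[(points > 0.0)]
            ok = cand[[continuous_density(float(g), post) >= dens0 for g in cand]]
            border = float(ok.max()) if ok.size else 0.0
        else:
            cand = points[(points < 0.0)]
            ok = cand[[continuous_density(float(g), post) >= dens0 for g in cand]]
            border = float(ok.min()) if ok.size else 0.0
    kappa = min(max(_kappa_from_border(post, border), 0.0), 1.0)
    t1, t2 = (0.0, border) if ghat > 0 else (border, 0.0)
    return EvidenceResult(kappa=kappa, moe=1.0 - kappa, t1=t1, t2=t2)


def bayes_factor(ghat: float, xty: float, xtx: float, sigma_e2: float) -> float:
    """log Bayes factor of {g = ghat} against {g = 0}.

    B = exp( -(1/(2 sigma_e^2)) (-2 y'x ghat + ghat^2 x'x) ), i.e. the
    likelihood ratio of the fitted one-locus model over the null; returned
    on the log scale.  B > 3 is the conventional threshold for a
    substantial effect.
    """
    if sigma_e2 <= 0.0:
        raise ValueError("sigma_e2 must be positive")
    return (2.0 * xty * ghat - ghat**2 * xtx) / (2.0 * sigma_e2)


# ---------------------------------------------------------------------------
# batch evaluation used by the significance module (vectorized over loci)


def posterior_stats_batch(Y, sigma2, prior: PriorSpec):
    """Vectorized (log_T1, log_T2, log_T3, ghat) over arrays Y, sigma2."""
    Y = np.asarray(Y, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    log_T1, log_T2, log_T3 = _log_T123(Y, sigma2, prior.gamma, prior.lam)
    log_Z = logsumexp(np.stack([log_T1, log_T2, np.broadcast_to(log_T3, log_T1.shape)]), axis=0)
    sigma = np.sqrt(sigma2)
    ghat = np.exp(log_T1 - log_Z) * _trunc_mean_batch(True, Y - prior.lam * sigma2, sigma) + np.exp(
        log_T2 - log_Z
    ) * _trunc_mean_batch(False, Y + prior.lam * sigma2, sigma)
    return log_T1, log_T2, log_T3, ghat


def hpd_credibility_batch(Y, sigma2, ghat, prior: PriorSpec, m_lower: float, m_upper: float, steps: int = 2000):
    """Vectorized kappa for many loci sharing one prior and one search grid.

    Performs the same grid comparison p(g|y) >= p(0|y) as the scalar
    routine, restricted to the Gaussian branch on the side of ghat, in
    chunks to bound memory.
    """
    Y = np.asarray(Y, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    ghat = np.asarray(ghat, dtype=float)
    lam = prior.lam
    points = np.linspace(m_lower, m_upper, steps + 1)
    pos = points[points > 0.0]
    neg = points[points < 0.0]
    kappa = np.zeros(Y.shape)
    border = np.zeros(Y.shape)
    for start in range(0, Y.size, 512):
        sl = slice(start, min(start + 512, Y.size))
        Ys, s2 = Y[sl], sigma2[sl]
        gh = ghat[sl]
        mu_pos = (Ys - lam * s2)[:, None]
        mu_neg = (Ys + lam * s2)[:, None]
        s2c = s2[:, None]
        b = np.zeros(Ys.shape)
        if pos.size:
            # f3(g) >= f3(0)  <=>  (g - mu)^2 <= mu^2 on the positive side
            ok = (pos[None, :] - mu_pos) ** 2 <= mu_pos**2
            ok &= gh[:, None] > 0
            any_ok = ok.any(axis=1)
            idx = np.where(ok, pos[None, :], -np.inf).max(axis=1)
            b = np.where((gh > 0) & any_ok, idx, b)
        if neg.size:
            ok = (neg[None, :] - mu_neg) ** 2 <= mu_neg**2
            ok &= gh[:, None] < 0
            any_ok = ok.any(axis=1)
            idx = np.where(ok, neg[None, :], np.inf).min(axis=1)
            b = np.where((gh < 0) & any_ok, idx, b)
        border[sl] = b
        # mass of the Gaussian branch between 0 and the border
        sigma = np.sqrt(s2)
        log_const = math.log(prior.gamma * lam / 2.0) + 0.5 * lam**2 * s2
        log_T1, log_T2, log_T3 = _log_T123(Ys, s2, prior.gamma, lam)
        log_py = log_const + logsumexp(np.stack([log_T1, log_T2, np.broadcast_to(log_T3, log_T1.shape)]), axis=0)
        with np.errstate(divide="ignore"):
            pos_mass = log_const - lam * Ys + _log_ndtr_diff(
                (np.maximum(b, 0.0) - (Ys - lam * s2)) / sigma, (0.0 - (Ys - lam * s2)) / sigma
            )
            neg_mass = log_const + lam * Ys + _log_ndtr_diff(
                (0.0 - (Ys + lam * s2)) / sigma, (np.minimum(b, 0.0) - (Ys + lam * s2)) / sigma
            )
        log_mass = np.where(b > 0, pos_mass, np.where(b < 0, neg_mass, -np.inf))
        kappa[sl] = np.clip(np.exp(log_mass - log_py), 0.0, 1.0)
    return kappa, border
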