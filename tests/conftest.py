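"""Shared fixtures and the independent quadrature oracle.

The oracle normalizes p(y|g) p(g|gamma) by adaptive quadrature, entirely
independently of the closed-form implementation: the posterior kernel is
written down directly (Gaussian likelihood kernel times the Laplace/spike
prior), shifted by its log maximum for stability, and integrated piecewise
with breakpoints at the kernel's stationary points.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from spikewgr.coding import GenotypeTable


def _log_kernel(g: float, Y: float, s2: float, lam: float) -> float:
    return -((g - Y) ** 2) / (2.0 * s2) - lam * abs(g)


def oracle_posterior(Y: float, s2: float, gamma: float, lam: float) -> dict:
    """Quadrature-normalized posterior of the one-locus spike+Laplace model.

    Returns normalization pieces, the posterior mean, the spike probability
    and a CDF callable.  The common likelihood constant 1/sqrt(2 pi s2)
    cancels between the continuous part and the spike and is dropped.
    """
    sigma = math.sqrt(s2)
    lo = min(0.0, Y) - 40.0 * sigma
    hi = max(0.0, Y) + 40.0 * sigma
    # breakpoints: stationary points of the Gaussian branches plus a
    # geometric ladder towards 0, so the adaptive rule cannot overlook a
    # boundary layer of width ~min(sigma, 1/lam) on a wide interval
    s_min = min(sigma, 1.0 / lam)
    ladder = [s_min * 10.0**k for k in range(-3, 6)]
    pts_neg = sorted(
        {p for p in [Y + lam * s2] + [-q for q in ladder] if lo < p < 0.0}
    )
    pts_pos = sorted({p for p in [Y - lam * s2] + ladder if 0.0 < p < hi})
    M = max(
        _log_kernel(0.0, Y, s2, lam),
        *(_log_kernel(p, Y, s2, lam) for p in pts_neg + pts_pos + [lo, hi]),
    )

    def f(g: float) -> float:
        return math.exp(_log_kernel(g, Y, s2, lam) - M)

    def piece(a: float, b: float, pts, weight=lambda g: 1.0) -> float:
        val, _ = quad(lambda g: weight(g) * f(g), a, b, points=pts or None, limit=400, epsabs=0.0, epsrel=1e-12)
        return val

    half = gamma * lam / 2.0
    i_neg = half * piece(lo, 0.0, pts_neg)
    i_pos = half * piece(0.0, hi, pts_pos)
    spike = (1.0 - gamma) * math.exp(-(Y**2) / (2.0 * s2) - M)
    Z = i_neg + i_pos + spike
    mean = (
        half * piece(lo, 0.0, pts_neg, weight=lambda g: g) + half * piece(0.0, hi, pts_pos, weight=lambda g: g)
    ) / Z

    def cdf(t: float) -> float:
        acc = half * piece(lo, min(t, 0.0), [p for p in pts_neg if p < t])
        if t > 0.0:
            acc += spike
            acc += half * piece(0.0, min(t, hi), [p for p in pts_pos if p < t])
        return acc / Z

    return {"mean": mean, "spike_prob": spike / Z, "cdf": cdf, "Z": Z, "scale": M}


def hwe_weights(f: float) -> np.ndarray:
    """Genotype frequencies of (AA, het, BB) at minor allele frequency f."""
    return np.array([f**2, 2.0 * f * (1.0 - f), (1.0 - f) ** 2])


def make_table(codes: np.ndarray, bp=None, chrom=None, maf=None) -> GenotypeTable:
    codes = np.asarray(codes)
    p = codes.shape[1]
    snp_map = pd.DataFrame(
        {
            "id": [f"snp{j}" for j in range(p)],
            "chrom": chrom if chrom is not None else np.ones(p, dtype=int),
            "cM": np.arange(p, dtype=float),
            "bp": bp if bp is not None else (np.arange(p, dtype=np.int64) * 1_000_000),
        }
    )
    return GenotypeTable(codes=codes, snp_map=snp_map, maf=maf)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_codes(rng: np.random.Generator, n: int, p: int, maf_range=(0.1, 0.5)) -> np.ndarray:
    """HWE genotypes at independent loci with frequencies in maf_range."""
    f = rng.uniform(*maf_range, size=p)
    u = rng.random((n, p))
    aa = u < f**2
    het = (u >= f**2) & (u < f**2 + 2 * f * (1 - f))
    return np.where(aa, 1, np.where(het, 0, -1)).astype(np.int8)
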