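"""Post-convergence marginal significance of every fitted effect.

After the Gauss-Seidel fit has converged, each coordinate j is tested
against its marginalized trait y_j = r + x_j ghat_j (r the final residual):
the credibility kappa of the HPD interval tangent to zero yields the
measure of evidence MOE = 1 - kappa (significant when MOE <= alpha), and
the marginal Bayes factor B_j flags a substantial effect when B_j > 3.

The HPD border search uses one grid per effect kind spanning
[10 min(ghat), 10 max(ghat)] over that kind's fitted effect vector with
2000 steps; coordinates for which those bounds do not straddle zero fall
back to a per-locus grid [-10(|ghat|+sigma), 10(|ghat|+sigma)].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coding import GenotypeTable, main_design
from .onelocus import (
    HpdGridSpec,
    LocusSufficientStats,
    PriorSpec,
    bayes_factor,
    hpd_credibility,
    hpd_credibility_batch,
    posterior_mean,
    posterior_stats_batch,
)
from .solver import FitResult, ModelSpec

DEFAULT_ALPHAS = (0.01, 0.05, 0.10, 0.20)
BF_THRESHOLD = 3.0

__all__ = ["EffectTestRecord", "test_all", "moe_bf_agreement", "DEFAULT_ALPHAS", "BF_THRESHOLD"]


@dataclass
class EffectTestRecord:
    """Significance summary of one fitted effect coordinate."""

    kind: str
    loci: tuple
    ghat: float
    kappa: float
    moe: float
    log_bayes_factor: float
    alphas: tuple = DEFAULT_ALPHAS
    bf_threshold: float = BF_THRESHOLD

    def significant_moe(self, alpha: float) -> bool:
        return self.moe <= alpha

    @property
    def significant_bf(self) -> bool:
        return self.log_bayes_factor > math.log(self.bf_threshold)


def _grid_bounds(ghats: np.ndarray, hpd_bound_factor: float) -> tuple[float, float] | None:
    if ghats.size == 0 or not np.any(ghats != 0.0):
        return None
    lo = hpd_bound_factor * float(ghats.min())
    hi = hpd_bound_factor * float(ghats.max())
    if not (lo < 0.0 < hi):
        return None
    return lo, hi


def _test_kind(
    kind: str,
    loci: list[tuple],
    xtr: np.ndarray,
    xtx: np.ndarray,
    ghat_fit: np.ndarray,
    sigma_e2: float,
    prior: PriorSpec,
    hpd_bound_factor: float,
    hpd_steps: int,
    alphas: tuple,
) -> list[EffectTestRecord]:
    """Vectorized testing of all coordinates of one effect kind."""
    xty = xtr + ghat_fit * xtx  # x_j' y_j with y_j = r + x_j ghat_j
    Y = xty / xtx
    sigma2 = sigma_e2 / xtx
    _, _, _, ghat = posterior_stats_batch(Y, sigma2, prior)
    log_bf = (2.0 * xty * ghat - ghat**2 * xtx) / (2.0 * sigma_e2)

    bounds = _grid_bounds(ghat, hpd_bound_factor)
    kappa = np.zeros(Y.shape)
    if bounds is not None:
        kappa, _ = hpd_credibility_batch(Y, sigma2, ghat, prior, bounds[0], bounds[1], hpd_steps)
    else:
        # shared bounds unusable (all estimates zero or one-signed): per-locus grid
        for idx in np.nonzero(ghat != 0.0)[0]:
            half = hpd_bound_factor * (abs(float(ghat[idx])) + math.sqrt(float(sigma2[idx])))
            post = posterior_mean(
                LocusSufficientStats(xtx=float(xtx[idx]), xty=float(xty[idx]), sigma_e2=sigma_e2), prior
            )
            ev = hpd_credibility(post, HpdGridSpec(-half, half, hpd_steps))
            kappa[idx] = ev.kappa

    return [
        EffectTestRecord(
            kind=kind,
            loci=loci[i],
            ghat=float(ghat[i]),
            kappa=float(kappa[i]),
            moe=1.0 - float(kappa[i]),
            log_bayes_factor=float(log_bf[i]),
            alphas=alphas,
        )
        for i in range(len(loci))
    ]


def test_all(
    fit: FitResult,
    genotypes: GenotypeTable,
    alphas: tuple = DEFAULT_ALPHAS,
    hpd_bound_factor: float = 10.0,
    hpd_steps: int = 2000,
) -> list[EffectTestRecord]:
    """Compute MOE and Bayes factor for every fitted coordinate.

    Tests are marginal: each coordinate is scored against the trait
    residualized for all other converged estimates, with the fit's final
    residual variance.  Returns one record per coordinate (main effects
    first, then epistatic pairs, kind-major).
    """
    if not fit.converged:
        import warnings

        warnings.warn("testing a non-converged fit; significance measures may be unstable")
    if any(not (0.0 < a < 1.0) for a in alphas):
        raise ValueError("alpha levels must lie in (0, 1)")
    model: ModelSpec = fit.model
    p = genotypes.p
    prior_main = fit.priors["main"]
    prior_epi = fit.priors.get("epi")
    r = fit.residual
    records: list[EffectTestRecord] = []

    designs = {k: main_design(genotypes, k) for k in ("additive", "dominance") if k in model.kinds}
    for kind, X in designs.items():
        xtr = X.T @ r
        xtx = (X * X).sum(axis=0)
        records.extend(
            _test_kind(
                kind,
                [(j,) for j in range(p)],
                xtr,
                xtx,
                np.asarray(fit.effects[kind]),
                fit.sigma_e2,
                prior_main,
                hpd_bound_factor,
                hpd_steps,
                alphas,
            )
        )

    if model.epi_kinds:
        from .solver import epistatic_sweep_order

        factors = {
            "epi_aa": ("additive", "additive"),
            "epi_ad": ("additive", "dominance"),
            "epi_da": ("dominance", "additive"),
            "epi_dd": ("dominance", "dominance"),
        }
        mats = {}
        for k in {f for e in model.epi_kinds for f in factors[e]}:
            mats[k] = designs.get(k)
            if mats[k] is None:
                mats[k] = main_design(genotypes, k)
        for kind in model.epi_kinds:
            eff = fit.effects[kind]
            loci, xtr_l, xtx_l, gh_l = [], [], [], []
            fa, fb = factors[kind]
            for _, i, j in epistatic_sweep_order(p, (kind,)):
                x = mats[fa][:, i] * mats[fb][:, j]
                xx = float(x @ x)
                if xx <= 0.0:
                    continue
                loci.append((i, j))
                xtr_l.append(float(x @ r))
                xtx_l.append(xx)
                gh_l.append(eff.get((i, j), 0.0))
            if loci:
                records.extend(
                    _test_kind(
                        kind,
                        loci,
                        np.array(xtr_l),
                        np.array(xtx_l),
                        np.array(gh_l),
                        fit.sigma_e2,
                        prior_epi,
                        hpd_bound_factor,
                        hpd_steps,
                        alphas,
                    )
                )
    return records


def moe_bf_agreement(records: list[EffectTestRecord], alpha: float = 0.05) -> dict:
    """Set relations between the MOE-significant and BF-significant effects.

    Empirically the BF set tends to contain the MOE set (the Bayes factor
    flags a few extra, mostly nonadditive, effects); this is reported, not
    enforced.  Coordinates with ghat = 0 belong to neither set.
    """
    moe_set = {(rec.kind, rec.loci) for rec in records if rec.ghat != 0.0 and rec.significant_moe(alpha)}
    bf_set = {(rec.kind, rec.loci) for rec in records if rec.ghat != 0.0 and rec.significant_bf}
    per_kind: dict[str, dict[str, int]] = {}
    for rec in records:
        d = per_kind.setdefault(rec.kind, {"moe": 0, "bf": 0, "both": 0})
        key = (rec.kind, rec.loci)
        d["moe"] += key in moe_set
        d["bf"] += key in bf_set
        d["both"] += key in moe_set and key in bf_set
    return {
        "alpha": alpha,
        "n_moe": len(moe_set),
        "n_bf": len(bf_set),
        "moe_subset_of_bf": moe_set <= bf_set,
        "moe_only": sorted(moe_set - bf_set),
        "bf_only": sorted(bf_set - moe_set),
        "per_kind": per_kind,
    }
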