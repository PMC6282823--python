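"""Marginalized Gauss-Seidel fitting of all genetic effects jointly.

Each coordinate (an additive, dominance or epistatic effect) is visited in
turn; its sufficient statistics are formed from the trait residualized for
every other current estimate, and the coordinate is replaced by its
closed-form one-locus posterior mean.  Starting from g = 0 everywhere, the
sweeps continue until the relative change of the stacked effect vector
(2-norm across all kinds) falls below ``tol`` or ``max_sweeps`` is reached.

Epistatic design columns are products of main-effect columns and are built
on the fly during each visit, never stored: model M3 has 2 p (p-1)
coordinates, which would not fit in memory at realistic p.

When a covariate design W is supplied, fixed effects and the residual
variance are refreshed once per sweep by the empirical-Bayes updates
b = (W'W)^{-1} W'(y - X g) and sigma_e^2 = e'e / (n - q).  Without
covariates, sigma_e2 is initialized from the centred-trait variance and
updated as e'e / n each sweep unless a fixed value is supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .coding import GenotypeTable, TraitVector, main_design, epistatic_values, EPI_KINDS
from .onelocus import PriorSpec, posterior_mean_scalar

logger = logging.getLogger(__name__)

MODEL_PRESETS = {
    "M1": ("additive",),
    "M2": ("additive", "dominance"),
    "M3": ("additive", "dominance") + EPI_KINDS,
}

__all__ = ["ModelSpec", "FitResult", "fit", "epistatic_sweep_order", "update_fixed_effects", "MODEL_PRESETS"]


@dataclass
class ModelSpec:
    """Which effect kinds to fit, their priors, and iteration controls.

    Presets: M1 = additive; M2 = additive + dominance; M3 = additive +
    dominance + all four epistatic kinds.  The default hyperparameters
    follow the rule gamma = 0.005, lambda = 2 p gamma for main effects and
    gamma = 1e-6, lambda = p (p - 1) gamma for epistatic effects, with p
    the number of SNPs after MAF filtering; pass explicit PriorSpec objects
    to override.
    """

    kinds: tuple[str, ...] = ("additive",)
    prior_main: PriorSpec | None = None
    prior_epi: PriorSpec | None = None
    gamma_main: float = 0.005
    gamma_epi: float = 1e-6
    max_sweeps: int = 500
    tol: float = 1e-4
    sigma_e2: float | None = None  # fixed residual variance; None = update each sweep

    def __post_init__(self) -> None:
        if isinstance(self.kinds, str):
            self.kinds = MODEL_PRESETS[self.kinds]
        self.kinds = tuple(self.kinds)
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        nonadd = set(self.kinds) - {"additive"}
        if nonadd and "additive" not in self.kinds:
            raise ValueError("dominance/epistasis requested without additive effects (models are nested)")

    @classmethod
    def preset(cls, name: str, **kwargs) -> "ModelSpec":
        return cls(kinds=MODEL_PRESETS[name], **kwargs)

    def resolve_priors(self, p: int) -> tuple[PriorSpec, PriorSpec | None]:
        main = self.prior_main or PriorSpec(self.gamma_main, 2.0 * p * self.gamma_main)
        epi = self.prior_epi
        if epi is None and any(k in EPI_KINDS for k in self.kinds):
            epi = PriorSpec(self.gamma_epi, p * (p - 1) * self.gamma_epi)
        return main, epi

    @property
    def epi_kinds(self) -> tuple[str, ...]:
        return tuple(k for k in self.kinds if k in EPI_KINDS)


@dataclass
class FitResult:
    """Converged effect estimates plus fit diagnostics.

    ``effects`` maps kind -> dense vector (main effects, length p) or
    dict {(i, j): ghat} holding only nonzero epistatic estimates.  The
    final residual satisfies residual = y - W b - sum_c x_c ghat_c.
    """

    effects: dict
    fixed: np.ndarray | None
    sigma_e2: float
    sweeps_run: int
    converged: bool
    residual: np.ndarray
    model: ModelSpec
    priors: dict = field(default_factory=dict)
    rel_changes: list = field(default_factory=list)

    def stacked(self) -> np.ndarray:
        parts = []
        for kind in self.model.kinds:
            eff = self.effects[kind]
            if isinstance(eff, dict):
                parts.append(np.array([v for _, v in sorted(eff.items())], dtype=float))
            else:
                parts.append(np.asarray(eff, dtype=float))
        return np.concatenate(parts) if parts else np.empty(0)


def epistatic_sweep_order(p: int, kinds: Sequence[str]) -> Iterator[tuple[str, int, int]]:
    """Deterministic enumeration of epistatic coordinates: kind-major, pairs
    i < j in lexicographic order; 4 kinds x p(p-1)/2 pairs = 2 p (p-1) total."""
    if p < 2:
        raise ValueError("epistasis requires p >= 2")
    for kind in kinds:
        if kind not in EPI_KINDS:
            raise ValueError(f"{kind!r} is not an epistatic kind")
        for i in range(p - 1):
            for j in range(i + 1, p):
                yield kind, i, j


def update_fixed_effects(
    y: np.ndarray, W: np.ndarray, genetic_part: np.ndarray
) -> tuple[np.ndarray, float]:
    """Empirical-Bayes refresh of fixed effects and residual variance.

    b = (W'W)^{-1} W'(y - X g); sigma_e^2 = e'e / (n - q) with
    e = y - W b - X g.  W must have full column rank and n > q.
    """
    n, q = W.shape
    if n <= q:
        raise ValueError("need more observations than covariates")
    rank = np.linalg.matrix_rank(W)
    if rank < q:
        _, R = np.linalg.qr(W)
        diag = np.abs(np.diag(R))
        bad = [j for j in range(q) if diag[j] < 1e-10 * max(diag.max(), 1.0)]
        raise ValueError(f"covariate design is rank deficient (rank {rank} < {q}); collinear columns: {bad}")
    ystar = y - genetic_part
    b, *_ = np.linalg.lstsq(W, ystar, rcond=None)
    e = ystar - W @ b
    return b, float(e @ e / (n - q))


def fit(
    genotypes: GenotypeTable,
    trait: TraitVector | np.ndarray,
    covariates: np.ndarray | None = None,
    model: ModelSpec | None = None,
) -> FitResult:
    """Fit the whole-genome regression by marginalized Gauss-Seidel sweeps.

    Per coordinate visit, with r the residual of all current estimates,
    the marginalized trait is y_j = r + x_j ghat_j(old); the update is the
    one-locus posterior mean given (x_j' x_j, x_j' y_j, sigma_e^2), and
    r <- r - x_j (ghat_new - ghat_old).  x'x uses the realized columns.
    """
    model = model or ModelSpec()
    y = trait.values if isinstance(trait, TraitVector) else np.asarray(trait, dtype=float)
    n, p = genotypes.n, genotypes.p
    if y.shape[0] != n:
        raise ValueError("trait length does not match the genotype table")
    prior_main, prior_epi = model.resolve_priors(p)

    designs = {}
    for kind in ("additive", "dominance"):
        if kind in model.kinds:
            designs[kind] = main_design(genotypes, kind)
    xtx = {kind: (X * X).sum(axis=0) for kind, X in designs.items()}

    update_sigma = model.sigma_e2 is None
    sigma_e2 = model.sigma_e2 if model.sigma_e2 is not None else float(np.var(y))
    if sigma_e2 <= 0:
        # degenerate all-equal trait: every Y is 0, all effects stay 0
        sigma_e2 = 1.0

    main_eff = {kind: np.zeros(p) for kind in designs}
    epi_eff: dict[str, dict[tuple[int, int], float]] = {kind: {} for kind in model.epi_kinds}
    b_hat = None
    r = y.copy()
    if covariates is not None:
        b_hat, sigma_e2_fx = update_fixed_effects(y, covariates, np.zeros(n))
        r = y - covariates @ b_hat
        if update_sigma:
            sigma_e2 = sigma_e2_fx

    epi_cols = {
        "epi_aa": ("additive", "additive"),
        "epi_ad": ("additive", "dominance"),
        "epi_da": ("dominance", "additive"),
        "epi_dd": ("dominance", "dominance"),
    }
    # main-effect matrices reused as factors of epistatic columns
    factor = {}
    if model.epi_kinds:
        need = {k for pair in (epi_cols[e] for e in model.epi_kinds) for k in pair}
        for kind in need:
            factor[kind] = designs.get(kind)
            if factor[kind] is None:
                factor[kind] = main_design(genotypes, kind)

    prev_main = {k: np.zeros(p) for k in designs}
    prev_epi: dict[str, dict[tuple[int, int], float]] = {k: {} for k in model.epi_kinds}
    converged = False
    sweeps = 0
    rel_changes: list[float] = []
    for sweeps in range(1, model.max_sweeps + 1):
        for kind, X in designs.items():
            eff = main_eff[kind]
            for j in range(p):
                x = X[:, j]
                old = eff[j]
                xty = float(x @ r) + old * xtx[kind][j]
                new = posterior_mean_scalar(xty / xtx[kind][j], sigma_e2 / xtx[kind][j], prior_main.gamma, prior_main.lam)
                if new != old:
                    r -= x * (new - old)
                    eff[j] = new
        if model.epi_kinds:
            for kind, i, j in epistatic_sweep_order(p, model.epi_kinds):
                fa, fb = epi_cols[kind]
                x = factor[fa][:, i] * factor[fb][:, j]
                xx = float(x @ x)
                if xx <= 0.0:
                    continue
                old = epi_eff[kind].get((i, j), 0.0)
                xty = float(x @ r) + old * xx
                new = posterior_mean_scalar(xty / xx, sigma_e2 / xx, prior_epi.gamma, prior_epi.lam)
                if new != old:
                    r -= x * (new - old)
                if new != 0.0:
                    epi_eff[kind][(i, j)] = new
                elif (i, j) in epi_eff[kind]:
                    del epi_eff[kind][(i, j)]

        genetic_part = y - r if covariates is None else (y - covariates @ b_hat) - r
        if covariates is not None:
            b_hat, s2 = update_fixed_effects(y, covariates, genetic_part)
            r = y - covariates @ b_hat - genetic_part
            if update_sigma:
                sigma_e2 = s2
        elif update_sigma:
            # floor keeps noiseless fits numerically sane
            sigma_e2 = max(float(r @ r / n), 1e-24 * float(np.var(y)), 1e-300)

        # relative change of the stacked effect vector; epistatic terms are
        # compared on the union of previous and current supports
        num2 = 0.0
        den2 = 0.0
        nonzero = 0
        for k in designs:
            num2 += float(np.sum((main_eff[k] - prev_main[k]) ** 2))
            den2 += float(np.sum(main_eff[k] ** 2))
            nonzero += int(np.sum(main_eff[k] != 0.0))
            prev_main[k] = main_eff[k].copy()
        for k in model.epi_kinds:
            keys = set(epi_eff[k]) | set(prev_epi[k])
            num2 += sum((epi_eff[k].get(key, 0.0) - prev_epi[k].get(key, 0.0)) ** 2 for key in keys)
            den2 += sum(v * v for v in epi_eff[k].values())
            nonzero += len(epi_eff[k])
            prev_epi[k] = dict(epi_eff[k])
        if num2 == 0.0 and den2 == 0.0:
            rel = 0.0
        elif den2 == 0.0:
            rel = np.inf
        else:
            rel = float(np.sqrt(num2 / den2))
        rel_changes.append(rel)
        logger.debug("sweep %d: rel change %.3e, sigma_e2 %.5g, nonzero %d", sweeps, rel, sigma_e2, nonzero)
        if rel < model.tol:
            converged = True
            break

    if not converged:
        logger.warning("did not converge in %d sweeps (last relative change %.3e)", sweeps, rel_changes[-1])

    effects: dict = {k: main_eff[k] for k in designs}
    effects.update(epi_eff)
    return FitResult(
        effects=effects,
        fixed=b_hat,
        sigma_e2=sigma_e2,
        sweeps_run=sweeps,
        converged=converged,
        residual=r,
        model=model,
        priors={"main": prior_main, "epi": prior_epi},
        rel_changes=rel_changes,
    )
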