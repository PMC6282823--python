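"""Scoring of a fit + significance scan against simulation truth.

Detection is judged with a physical window: a significant SNP counts as a
true positive for an effect kind if it lies within ``window_bp`` (default
100 kbp) of a causative variant carrying truth of that kind, on the same
chromosome.  An epistatic pair is a true positive only if both members fall
in windows of a truly interacting pair of the same kind (the strict,
kind-matched rule).  Overall sensitivity uses the union of significant SNPs
over all kinds against the union of causatives; specificity is the
true-negative rate over all tested coordinates outside the windows.

Also provided: the share of simulated genetic variance explained by the
significant effects (sigma2_sign), validation-set prediction accuracy, and
the resampling scheme for choosing the mixing proportion gamma.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coding import GenotypeTable, TraitVector, main_design, epistatic_values
from .significance import EffectTestRecord
from .solver import FitResult, ModelSpec, fit as gs_fit

__all__ = [
    "EvaluationReport",
    "score_detection",
    "explained_variance",
    "prediction_accuracy",
    "predict_genetic_values",
    "tune_gamma",
]

_EPI_FACTORS = {
    "epi_aa": ("additive", "additive"),
    "epi_ad": ("additive", "dominance"),
    "epi_da": ("dominance", "additive"),
    "epi_dd": ("dominance", "dominance"),
}


@dataclass
class EvaluationReport:
    """Sensitivity per kind and overall, overall specificity, and extras."""

    alpha: float
    rule: str
    sensitivity: dict = field(default_factory=dict)
    specificity: float = float("nan")
    n_true_positive: int = 0
    n_false_positive: int = 0
    n_negative: int = 0
    sigma2_sign: float | None = None
    accuracy: float | None = None

    def to_dict(self) -> dict:
        out = {"alpha": self.alpha, "rule": self.rule, "specificity": self.specificity}
        out.update({f"sensitivity_{k}": v for k, v in self.sensitivity.items()})
        if self.sigma2_sign is not None:
            out["sigma2_sign"] = self.sigma2_sign
        if self.accuracy is not None:
            out["accuracy"] = self.accuracy
        return out


def _is_significant(rec: EffectTestRecord, alpha: float, rule: str) -> bool:
    if rule == "moe":
        return rec.significant_moe(alpha)
    if rule == "bf":
        return rec.significant_bf
    raise ValueError("rule must be 'moe' or 'bf'")


def _window_matrix(snp_map: pd.DataFrame, c_bp, c_chrom, window_bp: int) -> np.ndarray:
    """Boolean (p x n_causative): SNP j within the window of causative c."""
    bp = snp_map["bp"].to_numpy()[:, None]
    chrom = snp_map["chrom"].to_numpy()[:, None]
    return (np.abs(bp - np.asarray(c_bp)[None, :]) <= window_bp) & (chrom == np.asarray(c_chrom)[None, :])


def score_detection(
    records: list[EffectTestRecord],
    snp_map: pd.DataFrame,
    truth: dict,
    window_bp: int = 100_000,
    alpha: float = 0.05,
    rule: str = "moe",
) -> EvaluationReport:
    """Sensitivity (per kind and overall) and overall specificity.

    ``truth`` is the simulator's truth dict: causative ids/bp/chrom, the
    per-kind effect vectors and the interacting pairs.  Missing truth is an
    error.
    """
    for key in ("causative_ids", "causative_bp", "causative_chrom"):
        if key not in truth:
            raise ValueError(f"truth lacks {key!r}")
    c_ids = list(truth["causative_ids"])
    near = _window_matrix(snp_map, truth["causative_bp"], truth["causative_chrom"], window_bp)
    nc = len(c_ids)

    # which causatives carry which kind of truth
    kind_truth: dict[str, np.ndarray] = {}
    if "additive_effects" in truth:
        kind_truth["additive"] = np.asarray(truth["additive_effects"]) != 0.0
        kind_truth["dominance"] = np.asarray(truth["dominance_effects"]) != 0.0
    else:  # genotype-only permutation runs: all causatives count for main kinds
        kind_truth["additive"] = np.ones(nc, dtype=bool)
        kind_truth["dominance"] = np.ones(nc, dtype=bool)
    true_pairs: dict[str, set[frozenset]] = {}
    for kind, plist in truth.get("epistasis_pairs", {}).items():
        true_pairs[kind] = {frozenset((c_ids.index(i), c_ids.index(j))) for i, j, _ in plist}

    detected_any = np.zeros(nc, dtype=bool)
    detected_kind: dict[str, np.ndarray] = {}
    n_neg = n_fp = n_tp = 0
    pair_hits: dict[str, set[frozenset]] = {k: set() for k in true_pairs}

    for rec in records:
        sig = _is_significant(rec, alpha, rule)
        if len(rec.loci) == 1:
            j = rec.loci[0]
            mask = kind_truth.get(rec.kind, np.zeros(nc, dtype=bool))
            hits = near[j] & mask
            if hits.any():
                if sig:
                    detected_kind.setdefault(rec.kind, np.zeros(nc, dtype=bool))[hits] = True
                    detected_any |= near[j]
                    n_tp += 1
            else:
                n_neg += 1
                if sig:
                    n_fp += 1
                    if sig and near[j].any():
                        detected_any |= near[j]
        else:
            i, j = rec.loci
            matched = {
                fs
                for fs in true_pairs.get(rec.kind, set())
                if (near[i, list(fs)[0]] and near[j, list(fs)[-1]])
                or (near[i, list(fs)[-1]] and near[j, list(fs)[0]])
            }
            if matched:
                if sig:
                    pair_hits[rec.kind] |= matched
                    detected_any |= near[i] | near[j]
                    n_tp += 1
            else:
                n_neg += 1
                if sig:
                    n_fp += 1
                    detected_any |= near[i] | near[j]

    sens: dict[str, float] = {}
    kinds_present = {rec.kind for rec in records}
    for kind in ("additive", "dominance"):
        if kind in kinds_present:
            mask = kind_truth[kind]
            found = detected_kind.get(kind, np.zeros(nc, dtype=bool))
            sens[kind] = float(found[mask].sum() / mask.sum()) if mask.sum() else float("nan")
    epi_kinds_present = [k for k in kinds_present if k.startswith("epi_")]
    if epi_kinds_present:
        # pooled over every truly interacting pair, whatever its kind
        total = sum(len(s) for s in true_pairs.values())
        hit = sum(len(s) for s in pair_hits.values())
        sens["epistasis"] = float(hit / total) if total else float("nan")
    sens["overall"] = float(detected_any.sum() / nc)

    spec = 1.0 if n_neg == 0 else 1.0 - n_fp / n_neg
    return EvaluationReport(
        alpha=alpha,
        rule=rule,
        sensitivity=sens,
        specificity=float(spec),
        n_true_positive=n_tp,
        n_false_positive=n_fp,
        n_negative=n_neg,
    )


def _column_values(table: GenotypeTable, kind: str, loci: tuple) -> np.ndarray:
    from .coding import additive_values, dominance_values

    if kind == "additive":
        return additive_values(table.codes[:, loci[0]], table.maf[loci[0]])
    if kind == "dominance":
        return dominance_values(table.codes[:, loci[0]], table.maf[loci[0]])
    i, j = loci
    return epistatic_values(kind, table.codes[:, i], table.codes[:, j], table.maf[i], table.maf[j])


def explained_variance(
    records: list[EffectTestRecord],
    table: GenotypeTable,
    true_genetic_values: np.ndarray,
    alpha: float = 0.05,
    rule: str = "moe",
) -> float:
    """sigma2_sign: variance of the significant effects' fitted genetic value
    over the training individuals, relative to the simulated genetic
    variance.  Can exceed 1 (overestimation is possible); no cap applied."""
    vG = float(np.var(true_genetic_values))
    if vG <= 0.0:
        raise ValueError("zero simulated genetic variance")
    part = np.zeros(table.n)
    for rec in records:
        if rec.ghat != 0.0 and _is_significant(rec, alpha, rule):
            part += rec.ghat * _column_values(table, rec.kind, rec.loci)
    return float(np.var(part) / vG)


def predict_genetic_values(fit: FitResult, table: GenotypeTable) -> np.ndarray:
    """Estimated genetic values X ghat over all fitted coordinates."""
    egv = np.zeros(table.n)
    designs = {}
    for kind in ("additive", "dominance"):
        if kind in fit.effects:
            designs[kind] = main_design(table, kind)
            egv += designs[kind] @ np.asarray(fit.effects[kind])
    for kind, eff in fit.effects.items():
        if not kind.startswith("epi_"):
            continue
        fa, fb = _EPI_FACTORS[kind]
        for k in (fa, fb):
            if k not in designs:
                designs[k] = main_design(table, k)
        for (i, j), w in eff.items():
            egv += w * designs[fa][:, i] * designs[fb][:, j]
    return egv


def prediction_accuracy(fit: FitResult, validation: GenotypeTable, true_genetic_values: np.ndarray) -> float:
    """Pearson correlation between predicted and simulated genetic values."""
    egv = predict_genetic_values(fit, validation)
    if np.std(egv) == 0.0 or np.std(true_genetic_values) == 0.0:
        warnings.warn("zero-variance prediction; accuracy reported as 0")
        return 0.0
    return float(np.corrcoef(egv, true_genetic_values)[0, 1])


def tune_gamma(
    genotypes: GenotypeTable,
    trait: TraitVector | np.ndarray,
    covariates: np.ndarray | None = None,
    gamma_grid=(0.001, 0.005, 0.01, 0.046, 0.1),
    split_seed: int = 0,
    model: ModelSpec | None = None,
    target: str = "main",
) -> tuple[float, pd.DataFrame]:
    """Choose gamma by a random half split.

    For each grid value, the model is fitted on a random half of the
    individuals (lambda re-derived from gamma by the kind's rule) and
    genetic values are predicted for the other half; the accuracy is the
    correlation between predicted values and the held-out phenotypes.  The
    gamma with the highest accuracy wins.  ``target`` selects whether the
    grid varies the main-effect or the epistasis gamma.
    """
    if len(gamma_grid) == 0:
        raise ValueError("gamma grid is empty")
    y = trait.values if isinstance(trait, TraitVector) else np.asarray(trait, dtype=float)
    n = genotypes.n
    if n < 4:
        raise ValueError("too few individuals to split")
    rng = np.random.default_rng(split_seed)
    perm = rng.permutation(n)
    train_idx, test_idx = perm[: n // 2], perm[n // 2 :]
    base = model or ModelSpec()
    t_train = GenotypeTable(
        codes=genotypes.codes[train_idx], snp_map=genotypes.snp_map, maf=genotypes.maf
    )
    t_test = GenotypeTable(codes=genotypes.codes[test_idx], snp_map=genotypes.snp_map, maf=genotypes.maf)
    rows = []
    for gamma in gamma_grid:
        kw = dict(
            kinds=base.kinds,
            max_sweeps=base.max_sweeps,
            tol=base.tol,
            gamma_main=gamma if target == "main" else base.gamma_main,
            gamma_epi=gamma if target == "epi" else base.gamma_epi,
        )
        res = gs_fit(
            t_train,
            y[train_idx],
            covariates[train_idx] if covariates is not None else None,
            ModelSpec(**kw),
        )
        egv = predict_genetic_values(res, t_test)
        acc = 0.0 if np.std(egv) == 0.0 else float(np.corrcoef(egv, y[test_idx])[0, 1])
        rows.append({"gamma": gamma, "accuracy": acc})
    table = pd.DataFrame(rows)
    accs = table["accuracy"].to_numpy()
    if accs.max() - accs.min() < 0.01:
        warnings.warn("accuracy is nearly flat over the gamma grid; the choice is weakly informed")
    best = float(table.loc[table["accuracy"].idxmax(), "gamma"])
    return best, table
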