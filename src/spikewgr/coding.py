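"""Standardized genotype coding for additive, dominance and epistatic effects.

Genotypes are stored as integer codes in {-1, 0, 1}: ``1`` is the homozygote
for the minor allele A (AA), ``-1`` the homozygote BB and ``0`` the
heterozygote.  Columns of the regression design are centred and scaled so
that, under Hardy-Weinberg proportions at the locus' minor allele frequency
*f*, each main-effect column has mean 0 and variance 1.  This exchangeability
across loci is what lets a single (gamma, lambda) prior govern all effects of
one kind.

Additive codes divide by s = sqrt(2 f (1-f)); dominance codes (Falconer's
parameterization of the heterozygote deviation) divide by s^2 = 2 f (1-f).
Epistatic columns are elementwise products of the two main-effect columns of
the corresponding kinds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MAIN_KINDS = ("additive", "dominance")
EPI_KINDS = ("epi_aa", "epi_ad", "epi_da", "epi_dd")
ALL_KINDS = MAIN_KINDS + EPI_KINDS

__all__ = [
    "GenotypeTable",
    "DesignColumn",
    "TraitVector",
    "estimate_maf",
    "orient_minor",
    "filter_maf",
    "code_additive",
    "code_dominance",
    "code_epistatic",
    "center_trait",
    "MAIN_KINDS",
    "EPI_KINDS",
    "ALL_KINDS",
]


@dataclass
class GenotypeTable:
    """Raw genotype codes plus SNP map and minor allele frequencies.

    Parameters
    ----------
    codes
        Integer matrix (n individuals x p SNPs) with entries in {-1, 0, 1}.
    snp_map
        DataFrame with one row per SNP and columns ``id``, ``chrom``,
        ``cM`` (genetic position in centimorgan) and ``bp``.
    maf
        Minor allele frequency per SNP, in (0, 0.5] after orientation.
        Computed by the method of moments if not supplied.
    individual_ids
        Optional identifiers, length n.
    """

    codes: np.ndarray
    snp_map: pd.DataFrame
    maf: np.ndarray | None = None
    individual_ids: np.ndarray | None = None
    monomorphic: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2 or self.codes.size == 0:
            raise ValueError("genotype matrix must be a nonempty 2-D array")
        if not np.isin(self.codes, (-1, 0, 1)).all():
            raise ValueError("genotype codes must be in {-1, 0, 1}")
        if len(self.snp_map) != self.codes.shape[1]:
            raise ValueError("snp_map length does not match number of SNPs")
        if self.maf is None:
            self.codes, self.maf = orient_minor(self.codes)
        else:
            self.maf = np.asarray(self.maf, dtype=float)
        self.monomorphic = self.maf <= 0.0

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def p(self) -> int:
        return self.codes.shape[1]

    def subset_snps(self, keep: np.ndarray) -> "GenotypeTable":
        """Restrict to the SNPs selected by boolean mask or index array."""
        return GenotypeTable(
            codes=self.codes[:, keep],
            snp_map=self.snp_map.iloc[np.atleast_1d(keep)].reset_index(drop=True)
            if np.asarray(keep).dtype != bool
            else self.snp_map.loc[keep].reset_index(drop=True),
            maf=self.maf[keep],
            individual_ids=self.individual_ids,
        )


@dataclass(frozen=True)
class DesignColumn:
    """A standardized predictor column addressed by effect kind and locus."""

    kind: str
    loci: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ALL_KINDS:
            raise ValueError(f"unknown effect kind {self.kind!r}")


@dataclass(frozen=True)
class TraitVector:
    """Trait values centred by the population mean."""

    values: np.ndarray
    center: float


def estimate_maf(codes: np.ndarray) -> np.ndarray:
    """Method-of-moments allele frequency f_j = (1/2n) sum_i (X_ij + 1).

    Returns the frequency of the labelled A allele; values above 0.5 signal
    that the labels need swapping (see :func:`orient_minor`).
    """
    codes = np.asarray(codes)
    if codes.size == 0:
        raise ValueError("empty genotype matrix")
    if codes.ndim == 1:
        codes = codes[:, None]
    return (codes + 1).mean(axis=0) / 2.0


def orient_minor(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orient each SNP so the labelled A allele is the minor one.

    SNPs whose raw A-allele frequency exceeds 0.5 have their codes negated
    and frequency replaced by 1 - f.  Idempotent.  Returns (codes, maf);
    monomorphic SNPs keep f = 0 and are flagged on the GenotypeTable.
    """
    codes = np.asarray(codes)
    f = estimate_maf(codes)
    flip = f > 0.5
    if flip.any():
        codes = codes.copy()
        codes[:, flip] *= -1
        f = np.where(flip, 1.0 - f, f)
    return codes, f


def filter_maf(table: GenotypeTable, threshold: float) -> GenotypeTable:
    """Drop SNPs with minor allele frequency <= ``threshold``.

    The strict "<=" follows the convention of removing SNPs at the boundary;
    ``threshold=0`` therefore removes exactly the monomorphic SNPs.  SNP
    order is preserved.  If the snp_map carries a boolean ``causative``
    column, dropped causatives are recorded in ``table.snp_map.attrs``.
    """
    if not (0.0 <= threshold < 0.5):
        raise ValueError("MAF threshold must lie in [0, 0.5)")
    keep = table.maf > threshold
    out = table.subset_snps(keep)
    if "causative" in table.snp_map.columns:
        dropped = table.snp_map.loc[~keep & table.snp_map["causative"], "id"]
        out.snp_map.attrs["dropped_causatives"] = list(dropped)
    return out


def _check_f(f: float) -> None:
    if not (0.0 < f < 1.0):
        raise ValueError(f"allele frequency {f} gives a zero-variance column")


def additive_values(codes: np.ndarray, f: float) -> np.ndarray:
    """Standardized additive codes: AA -> 2(1-f)/s, het -> (1-2f)/s, BB -> -2f/s
    with s = sqrt(2 f (1-f))."""
    _check_f(f)
    s = np.sqrt(2.0 * f * (1.0 - f))
    codes = np.asarray(codes, dtype=float)
    return (codes + (1.0 - 2.0 * f)) / s


def dominance_values(codes: np.ndarray, f: float) -> np.ndarray:
    """Falconer dominance codes scaled by s^2 = 2 f (1-f):
    AA -> -2(1-f)^2/s^2, het -> 2f(1-f)/s^2, BB -> -2f^2/s^2."""
    _check_f(f)
    s2 = 2.0 * f * (1.0 - f)
    codes = np.asarray(codes)
    out = np.empty(codes.shape, dtype=float)
    out[codes == 1] = -2.0 * (1.0 - f) ** 2 / s2
    out[codes == 0] = 1.0
    out[codes == -1] = -2.0 * f**2 / s2
    return out


def code_additive(codes: np.ndarray, f: float, locus: int = 0) -> DesignColumn:
    return DesignColumn("additive", (locus,), additive_values(codes, f))


def code_dominance(codes: np.ndarray, f: float, locus: int = 0) -> DesignColumn:
    return DesignColumn("dominance", (locus,), dominance_values(codes, f))


_EPI_FACTORS = {
    "aa": (additive_values, additive_values),
    "ad": (additive_values, dominance_values),
    "da": (dominance_values, additive_values),
    "dd": (dominance_values, dominance_values),
}


def epistatic_values(
    kind: str, codes_i: np.ndarray, codes_j: np.ndarray, f_i: float, f_j: float
) -> np.ndarray:
    """Product coding for a two-locus interaction of the given kind."""
    kind = kind.removeprefix("epi_")
    fun_i, fun_j = _EPI_FACTORS[kind]
    return fun_i(codes_i, f_i) * fun_j(codes_j, f_j)


def code_epistatic(
    kind: str,
    codes_i: np.ndarray,
    codes_j: np.ndarray,
    f_i: float,
    f_j: float,
    loci: tuple[int, int] = (0, 1),
) -> DesignColumn:
    if loci[0] == loci[1]:
        raise ValueError("epistatic pair must involve two distinct loci")
    key = kind if kind.startswith("epi_") else f"epi_{kind}"
    return DesignColumn(key, tuple(loci), epistatic_values(kind, codes_i, codes_j, f_i, f_j))


def center_trait(raw: Sequence[float]) -> TraitVector:
    """Centre a trait vector by its arithmetic mean (the population mean)."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or raw.size < 2:
        raise ValueError("trait must be a vector of length >= 2")
    m = float(raw.mean())
    return TraitVector(values=raw - m, center=m)


def main_design(table: GenotypeTable, kind: str) -> np.ndarray:
    """Full n x p standardized design matrix for one main-effect kind."""
    fun = {"additive": additive_values, "dominance": dominance_values}[kind]
    cols = [fun(table.codes[:, j], table.maf[j]) for j in range(table.p)]
    return np.column_stack(cols) if cols else np.empty((table.n, 0))
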