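"""Forward-in-time simulation of a livestock-like SNP panel and trait.

The generator emulates a dairy-cattle study design: a dense biallelic SNP
panel on a multi-chromosome genome (default 52,773 SNPs on 30 Morgan), 400
burn-in generations of random mating among 100 individuals with Haldane
recombination and per-SNP mutation to build up linkage disequilibrium,
followed by 4 final generations in which 50 sires are each mated to 20 dams
(multiple half-sib families, 1,000 offspring per generation).  Generations
1-2 of the final phase form the training set (n = 2,000) and generations
3-4 the validation set.

The SNP panel is thinned to every 10th SNP (causative variants always
kept), and SNPs with minor allele frequency <= 0.05 in the training set are
removed.  Twenty-three causative variants carry additive and dominance
effects; for each of the four epistatic kinds, six interacting pairs are
drawn from the causatives.  Effect sizes are standard normal draws rescaled
blockwise so that dominance contributes ~10% and epistasis ~29% of the
realized genetic variance; residual noise is scaled to hit the requested
broad-sense heritability exactly on the realized training variance.

Physical coordinates use a fixed 1 cM = 1 Mbp map (30 Morgan -> 3 Gbp), so
the 100-kbp evaluation window is well defined; after 10x thinning a window
usually contains only the causative SNP itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coding import (
    GenotypeTable,
    TraitVector,
    additive_values,
    dominance_values,
    estimate_maf,
    filter_maf,
)

EPI_KINDS = ("epi_aa", "epi_ad", "epi_da", "epi_dd")
MORGAN_TO_BP = 100_000_000  # 1 cM = 1 Mbp

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_population",
    "attach_trait",
    "permute_genotypes",
    "apply_permutation",
]


@dataclass
class SimulationConfig:
    """Study-design parameters; defaults are the full cattle-like design."""

    n_snps: int = 52_773
    genome_morgan: float = 30.0
    n_chromosomes: int = 30
    burnin_generations: int = 400
    burnin_popsize: int = 100
    final_generations: int = 4
    n_sires: int = 50
    dams_per_sire: int = 20
    thin_every: int = 10
    maf_threshold: float = 0.05
    n_causative: int = 23
    epi_pairs_per_kind: int = 6
    dominance_var_fraction: float = 0.10
    epistasis_var_fraction: float = 0.29
    h2: float = 0.5
    mutation_rate: float = 2e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.h2 <= 1.0):
            raise ValueError("h2 must lie in (0, 1]")
        if self.dominance_var_fraction + self.epistasis_var_fraction >= 1.0:
            raise ValueError("variance fractions must sum to less than 1")
        for name in ("n_snps", "burnin_popsize", "final_generations", "n_sires", "dams_per_sire", "thin_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def offspring_per_generation(self) -> int:
        return self.n_sires * self.dams_per_sire

    def reduced(self, **overrides) -> "SimulationConfig":
        """Copy with overrides; convenience for desk-scale runs."""
        from dataclasses import asdict

        params = asdict(self)
        params.update(overrides)
        return SimulationConfig(**params)


@dataclass
class SimulatedDataset:
    """Training/validation genotypes plus (after attach_trait) trait and truth."""

    config: SimulationConfig
    training: GenotypeTable
    validation: GenotypeTable
    pedigree: pd.DataFrame
    trait: TraitVector | None = None
    genetic_values_training: np.ndarray | None = None
    genetic_values_validation: np.ndarray | None = None
    truth: dict = field(default_factory=dict)


def _snp_positions(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Jittered-uniform genetic positions on equal-length chromosomes, 1 cM = 1 Mbp."""
    chrom_len = cfg.genome_morgan / cfg.n_chromosomes
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_snps // cfg.n_chromosomes)
    per_chrom[: cfg.n_snps % cfg.n_chromosomes] += 1
    rows = []
    for c, m in enumerate(per_chrom):
        pos = np.sort(rng.uniform(0.0, chrom_len, m))
        rows.append(
            pd.DataFrame(
                {
                    "chrom": c + 1,
                    "morgan": pos,
                    "bp": np.round(pos * MORGAN_TO_BP).astype(np.int64),
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    out.insert(0, "id", [f"snp{i}" for i in range(len(out))])
    out["cM"] = out["morgan"] * 100.0
    return out


def _switch_probs(snp_map: pd.DataFrame) -> np.ndarray:
    """Per-interval Haldane switch probabilities r = (1 - exp(-2d))/2;
    chromosome starts get r = 0.5 (independent segregation)."""
    d = np.diff(snp_map["morgan"].to_numpy(), prepend=0.0)
    r = 0.5 * (1.0 - np.exp(-2.0 * d))
    new_chrom = np.diff(snp_map["chrom"].to_numpy(), prepend=0) != 0
    r[0] = 0.5
    r[new_chrom] = 0.5
    return r


def _meiosis(haps: np.ndarray, r: np.ndarray, mu: float, rng: np.random.Generator) -> np.ndarray:
    """One gamete per input individual.

    haps: (m, 2, p) parental haplotypes.  Crossovers follow a Markov chain
    over SNP intervals with switch probability r (Haldane, no interference);
    each allele then mutates (flips) independently with probability mu.
    """
    m, _, p = haps.shape
    switches = (rng.random((m, p)) < r).astype(np.uint8)
    inherit = np.bitwise_xor.accumulate(switches, axis=1)
    gametes = np.where(inherit == 0, haps[:, 0, :], haps[:, 1, :])
    if mu > 0.0:
        flips = rng.random((m, p)) < mu
        gametes = gametes ^ flips
    return gametes.astype(np.uint8)


def _random_mating(haps: np.ndarray, r: np.ndarray, mu: float, rng: np.random.Generator) -> np.ndarray:
    n = haps.shape[0]
    dad = rng.integers(0, n, n)
    mom = (dad + rng.integers(1, n, n)) % n  # distinct parents
    g_dad = _meiosis(haps[dad], r, mu, rng)
    g_mom = _meiosis(haps[mom], r, mu, rng)
    return np.stack([g_dad, g_mom], axis=1)


def simulate_population(config: SimulationConfig) -> SimulatedDataset:
    """Simulate genotypes only (use :func:`attach_trait` for the phenotype).

    Returns a dataset whose training/validation tables are thinned (every
    ``thin_every``-th SNP plus all causatives) and MAF-filtered on the
    training set; causative variants are drawn among SNPs polymorphic
    enough to survive the filter and are marked in ``snp_map['causative']``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    snp_map = _snp_positions(cfg, rng)
    p = len(snp_map)
    r = _switch_probs(snp_map)

    haps = (rng.random((cfg.burnin_popsize, 2, p)) < 0.5).astype(np.uint8)
    for _ in range(cfg.burnin_generations):
        haps = _random_mating(haps, r, cfg.mutation_rate, rng)

    n_off = cfg.offspring_per_generation
    gen_codes = []
    ped_rows = []
    for gen in range(cfg.final_generations):
        pool = haps.shape[0]
        sires = rng.choice(pool, size=min(cfg.n_sires, pool), replace=False)
        n_dams = n_off
        dams = rng.choice(pool, size=n_dams, replace=n_dams > pool)
        sire_of = np.repeat(sires, cfg.dams_per_sire)[:n_off]
        g_sire = _meiosis(haps[sire_of], r, cfg.mutation_rate, rng)
        g_dam = _meiosis(haps[dams], r, cfg.mutation_rate, rng)
        haps = np.stack([g_sire, g_dam], axis=1)
        gen_codes.append(haps.sum(axis=1).astype(np.int8) - 1)
        ped_rows.append(
            pd.DataFrame(
                {
                    "generation": gen + 1,
                    "individual": np.arange(n_off),
                    "sire": sire_of,
                    "dam": dams,
                }
            )
        )
    pedigree = pd.concat(ped_rows, ignore_index=True)

    n_train_gens = cfg.final_generations // 2
    train_codes = np.concatenate(gen_codes[:n_train_gens], axis=0)
    valid_codes = np.concatenate(gen_codes[n_train_gens:], axis=0)

    # orient to the minor allele using the training set, applied to both sets
    f_raw = estimate_maf(train_codes)
    flip = f_raw > 0.5
    train_codes = np.where(flip, -train_codes, train_codes)
    valid_codes = np.where(flip, -valid_codes, valid_codes)
    f = np.where(flip, 1.0 - f_raw, f_raw)

    eligible = np.nonzero(f > cfg.maf_threshold)[0]
    if eligible.size < cfg.n_causative:
        raise RuntimeError("too few polymorphic SNPs to place the causative variants")
    causative = np.sort(rng.choice(eligible, size=cfg.n_causative, replace=False))
    snp_map = snp_map.copy()
    snp_map["causative"] = False
    snp_map.loc[causative, "causative"] = True

    keep = np.union1d(np.arange(0, p, cfg.thin_every), causative)
    training = GenotypeTable(
        codes=train_codes[:, keep], snp_map=snp_map.iloc[keep].reset_index(drop=True), maf=f[keep]
    )
    validation = GenotypeTable(
        codes=valid_codes[:, keep], snp_map=snp_map.iloc[keep].reset_index(drop=True), maf=f[keep]
    )
    training = filter_maf(training, cfg.maf_threshold)
    kept_ids = set(training.snp_map["id"])
    vkeep = validation.snp_map["id"].isin(kept_ids).to_numpy()
    validation = validation.subset_snps(vkeep)

    truth = {
        "causative_ids": list(snp_map.loc[causative, "id"]),
        "causative_bp": snp_map.loc[causative, "bp"].to_numpy(),
        "causative_chrom": snp_map.loc[causative, "chrom"].to_numpy(),
        "n_snps_thinned": int(len(keep)),
        "n_snps_analyzed": int(training.p),
    }
    return SimulatedDataset(
        config=cfg, training=training, validation=validation, pedigree=pedigree, truth=truth
    )


def _design_at(table: GenotypeTable, cols: np.ndarray, maf: np.ndarray, kind: str) -> np.ndarray:
    fun = additive_values if kind == "additive" else dominance_values
    return np.column_stack([fun(table.codes[:, j], maf[i]) for i, j in enumerate(cols)])


def attach_trait(dataset: SimulatedDataset, seed: int | None = None) -> SimulatedDataset:
    """Draw effect sizes, build genetic values and add the residual noise.

    Effects are standard-normal draws per causative (additive and dominance)
    and per interacting pair; the dominance and epistasis blocks are
    rescaled by a fixed-point iteration until their realized shares of the
    training genetic variance match the configured fractions, and the
    residual vector is scaled so the realized broad-sense heritability
    equals ``config.h2`` exactly up to the genetic-residual sample
    covariance.
    """
    cfg = dataset.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    train, valid = dataset.training, dataset.validation
    ids = list(train.snp_map["id"])
    cidx = np.array([ids.index(s) for s in dataset.truth["causative_ids"]])
    cmaf = train.maf[cidx]
    nc = len(cidx)

    Xa_t = _design_at(train, cidx, cmaf, "additive")
    Xd_t = _design_at(train, cidx, cmaf, "dominance")
    Xa_v = _design_at(valid, cidx, cmaf, "additive")
    Xd_v = _design_at(valid, cidx, cmaf, "dominance")

    a_eff = rng.standard_normal(nc)
    d_eff = rng.standard_normal(nc)
    pairs: dict[str, list[tuple[int, int]]] = {}
    e_eff: dict[str, np.ndarray] = {}
    for kind in EPI_KINDS:
        chosen = []
        for _ in range(cfg.epi_pairs_per_kind):
            i, j = rng.choice(nc, size=2, replace=False)
            chosen.append((int(i), int(j)))
        pairs[kind] = chosen
        e_eff[kind] = rng.standard_normal(cfg.epi_pairs_per_kind)

    def epi_part(Xa, Xd):
        part = np.zeros(Xa.shape[0])
        fac = {"epi_aa": (Xa, Xa), "epi_ad": (Xa, Xd), "epi_da": (Xd, Xa), "epi_dd": (Xd, Xd)}
        for kind in EPI_KINDS:
            A, B = fac[kind]
            for w, (i, j) in zip(e_eff[kind], pairs[kind]):
                part += w * A[:, i] * B[:, j]
        return part

    Ga, Gd, Ge = Xa_t @ a_eff, Xd_t @ d_eff, epi_part(Xa_t, Xd_t)
    fd, fe = cfg.dominance_var_fraction, cfg.epistasis_var_fraction
    cd = 1.0 if (fd > 0 and Gd.var() > 0) else 0.0
    ce = 1.0 if (fe > 0 and Ge.var() > 0) else 0.0
    for _ in range(60):
        G = Ga + cd * Gd + ce * Ge
        vG = G.var()
        share_d = (cd**2) * Gd.var() / vG
        share_e = (ce**2) * Ge.var() / vG
        if abs(share_d - fd) < 1e-10 and abs(share_e - fe) < 1e-10:
            break
        if cd > 0:
            cd *= np.sqrt(fd / share_d)
        if ce > 0:
            ce *= np.sqrt(fe / share_e)
    G_train = Ga + cd * Gd + ce * Ge
    G_valid = Xa_v @ a_eff + cd * (Xd_v @ d_eff) + ce * epi_part(Xa_v, Xd_v)

    vG = G_train.var()
    if vG <= 0:
        raise RuntimeError("degenerate genotypes: zero genetic variance")
    sigma_e2 = vG * (1.0 - cfg.h2) / cfg.h2
    if sigma_e2 > 0:
        e = rng.standard_normal(train.n)
        e = (e - e.mean()) * np.sqrt(sigma_e2 / e.var())
    else:
        e = np.zeros(train.n)
    y = G_train + e

    dataset.trait = TraitVector(values=y - y.mean(), center=float(y.mean()))
    dataset.genetic_values_training = G_train
    dataset.genetic_values_validation = G_valid
    dataset.truth.update(
        {
            "additive_effects": a_eff,
            "dominance_effects": cd * d_eff,
            "epistasis_pairs": {
                kind: [
                    (dataset.truth["causative_ids"][i], dataset.truth["causative_ids"][j], float(ce * w))
                    for (i, j), w in zip(pairs[kind], e_eff[kind])
                ]
                for kind in EPI_KINDS
            },
            "sigma_e2": float(sigma_e2),
            "var_genetic": float(vG),
            "realized_h2": float(vG / y.var()),
            "share_dominance": float((cd**2) * Gd.var() / vG),
            "share_epistasis": float((ce**2) * Ge.var() / vG),
        }
    )
    return dataset


def apply_permutation(dataset: SimulatedDataset, perm: np.ndarray) -> SimulatedDataset:
    """Dataset whose training genotype rows are reordered by ``perm``; the
    trait stays attached to the original individuals."""
    new_train = GenotypeTable(
        codes=dataset.training.codes[perm],
        snp_map=dataset.training.snp_map,
        maf=dataset.training.maf,
    )
    return SimulatedDataset(
        config=dataset.config,
        training=new_train,
        validation=dataset.validation,
        pedigree=dataset.pedigree,
        trait=dataset.trait,
        genetic_values_training=dataset.genetic_values_training,
        genetic_values_validation=dataset.genetic_values_validation,
        truth=dataset.truth,
    )


def permute_genotypes(dataset: SimulatedDataset, n_permutations: int, seed: int = 0):
    """Yield datasets with genotype rows shuffled against the phenotype.

    Each permutation is reproducible from (seed, index) alone.  Allele
    frequencies are invariant under row permutation, so the standardized
    design is the same matrix with reordered rows.
    """
    for idx in range(n_permutations):
        rng = np.random.default_rng(np.random.SeedSequence((seed, idx)))
        perm = rng.permutation(dataset.training.n)
        yield apply_permutation(dataset, perm)
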