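"""Forward simulator: meiosis, LD, family structure, trait architecture."""

import numpy as np
import pytest

from spikewgr.coding import additive_values, estimate_maf
from spikewgr.simulate import (
    SimulationConfig,
    _meiosis,
    apply_permutation,
    attach_trait,
    permute_genotypes,
    simulate_population,
)

SMALL = dict(
    n_snps=400,
    genome_morgan=0.24,  # preserves the full design's SNP density
    n_chromosomes=2,
    burnin_generations=60,
    burnin_popsize=60,
    n_sires=10,
    dams_per_sire=10,
    thin_every=2,
    n_causative=8,
    epi_pairs_per_kind=2,
)


def small_config(**over) -> SimulationConfig:
    params = {**SMALL, **over}
    return SimulationConfig(**params)


def test_meiosis_without_recombination_copies_a_parent(rng):
    p = 50
    haps = rng.integers(0, 2, size=(20, 2, p)).astype(np.uint8)
    r = np.zeros(p)
    r[0] = 0.5  # random start, no recombination afterwards
    gametes = _meiosis(haps, r, 0.0, rng)
    for g, pair in zip(gametes, haps):
        assert np.array_equal(g, pair[0]) or np.array_equal(g, pair[1])


def test_crossover_count_matches_map_length(rng):
    """Expected crossovers per meiosis equal the summed interval probabilities,
    which approach the map length (in Morgan) for a dense map."""
    p, L = 2000, 2.0
    pos = np.sort(rng.uniform(0, L, p))
    d = np.diff(pos, prepend=0.0)
    r = 0.5 * (1 - np.exp(-2 * d))
    r[0] = 0.0  # fix the start so every switch is a crossover
    haps = np.zeros((10_000, 2, p), dtype=np.uint8)
    haps[:, 1, :] = 1  # fully heterozygous: gamete value reveals the inheritance
    gametes = _meiosis(haps, r, 0.0, rng)
    crossovers = (np.diff(gametes.astype(int), axis=1) != 0).sum(axis=1)
    expect = r.sum()
    assert expect == pytest.approx(L, rel=0.05)
    se = np.sqrt(expect / 10_000)
    assert abs(crossovers.mean() - expect) < 3 * se + 0.02


def test_reproducible_from_seed():
    cfg = small_config(seed=5)
    a = attach_trait(simulate_population(cfg))
    b = attach_trait(simulate_population(cfg))
    np.testing.assert_array_equal(a.training.codes, b.training.codes)
    np.testing.assert_array_equal(a.validation.codes, b.validation.codes)
    np.testing.assert_allclose(a.trait.values, b.trait.values)


def test_half_sib_structure():
    ds = simulate_population(small_config(seed=3))
    cfg = ds.config
    for gen, sub in ds.pedigree.groupby("generation"):
        assert len(sub) == cfg.offspring_per_generation
        assert sub["sire"].nunique() <= cfg.n_sires
        # each sire serves a full half-sib family
        assert sub.groupby("sire").size().max() >= cfg.dams_per_sire
    assert ds.training.n == 2 * cfg.offspring_per_generation
    assert ds.validation.n == 2 * cfg.offspring_per_generation


def test_training_validation_split_disjoint_generations():
    ds = simulate_population(small_config(seed=4))
    assert ds.training.n + ds.validation.n == 4 * ds.config.offspring_per_generation


def test_ld_decays_with_distance():
    from scipy.stats import spearmanr

    ds = simulate_population(small_config(seed=7, n_chromosomes=1, genome_morgan=0.5))
    table = ds.training
    chrom1 = table.snp_map["chrom"] == 1
    idx = np.nonzero(chrom1.to_numpy())[0][:120]
    X = np.column_stack([additive_values(table.codes[:, j], table.maf[j]) for j in idx])
    pos = table.snp_map["morgan"].to_numpy()[idx] if "morgan" in table.snp_map else table.snp_map["cM"].to_numpy()[idx] / 100
    corr = np.corrcoef(X, rowvar=False) ** 2
    iu = np.triu_indices(len(idx), k=1)
    dist = np.abs(pos[:, None] - pos[None, :])[iu]
    r2 = corr[iu]
    bins = np.quantile(dist, np.linspace(0, 1, 9))
    which = np.clip(np.digitize(dist, bins[1:-1]), 0, 7)
    means = [r2[which == b].mean() for b in range(8)]
    rho, _ = spearmanr(np.arange(8), means)
    assert rho < 0


def test_post_filter_retention_matches_design():
    """At the design's SNP density, ~85% of thinned SNPs survive the MAF filter
    (the full design removes ~793 of 5,227 on average)."""
    fracs = []
    for seed in (1, 2):
        cfg = SimulationConfig(
            n_snps=3000, genome_morgan=1.8, n_chromosomes=2, seed=seed
        )
        ds = simulate_population(cfg)
        fracs.append(ds.training.p / ds.truth["n_snps_thinned"])
    target = 1.0 - 793.0 / 5227.0
    assert abs(np.mean(fracs) - target) < 0.15 * target


def test_causatives_survive_thinning_and_filter():
    ds = simulate_population(small_config(seed=9))
    ids = set(ds.training.snp_map["id"])
    assert set(ds.truth["causative_ids"]) <= ids
    assert ds.training.snp_map["causative"].sum() == ds.config.n_causative


def test_trait_heritability_and_variance_shares():
    h2s, dshares, eshares = [], [], []
    for seed in range(12):
        ds = attach_trait(simulate_population(small_config(seed=100 + seed)))
        h2s.append(ds.truth["realized_h2"])
        dshares.append(ds.truth["share_dominance"])
        eshares.append(ds.truth["share_epistasis"])
    assert abs(np.mean(h2s) - 0.5) < 0.02
    assert abs(np.mean(dshares) - 0.10) < 0.03
    assert abs(np.mean(eshares) - 0.29) < 0.03


def test_full_heritability_means_no_noise():
    ds = attach_trait(simulate_population(small_config(seed=2, h2=1.0)))
    centered_g = ds.genetic_values_training - ds.genetic_values_training.mean()
    np.testing.assert_allclose(ds.trait.values, centered_g, atol=1e-9)


def test_permutations_reproducible_and_frequency_invariant():
    ds = attach_trait(simulate_population(small_config(seed=6)))
    first = [d.training.codes.copy() for d in permute_genotypes(ds, 2, seed=11)]
    second = [d.training.codes.copy() for d in permute_genotypes(ds, 2, seed=11)]
    for a, b in zip(first, second):
        np.testing.assert_array_equal(a, b)
    np.testing.assert_allclose(estimate_maf(first[0]), estimate_maf(ds.training.codes))
    ident = apply_permutation(ds, np.arange(ds.training.n))
    np.testing.assert_array_equal(ident.training.codes, ds.training.codes)


def test_permutation_breaks_association():
    ds = attach_trait(simulate_population(small_config(seed=8)))
    y = ds.trait.values
    cidx = [list(ds.training.snp_map["id"]).index(s) for s in ds.truth["causative_ids"]]
    cors = []
    for d in permute_genotypes(ds, 10, seed=3):
        X = np.column_stack(
            [additive_values(d.training.codes[:, j], d.training.maf[j]) for j in cidx]
        )
        cors.append(np.abs(np.corrcoef(X.T, y)[:-1, -1]).mean())
    assert np.mean(cors) < 3.0 / np.sqrt(ds.training.n)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(h2=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(dominance_var_fraction=0.6, epistasis_var_fraction=0.5)
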