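"""Detection scoring, explained variance, prediction accuracy, gamma tuning."""

import numpy as np
import pandas as pd
import pytest

from spikewgr.coding import additive_values
from spikewgr.evaluate import (
    explained_variance,
    prediction_accuracy,
    score_detection,
    tune_gamma,
)
from spikewgr.significance import EffectTestRecord
from spikewgr.solver import FitResult, ModelSpec
from spikewgr.onelocus import PriorSpec

from conftest import make_table, random_codes


def rec(kind, loci, moe, ghat=0.3, log_bf=0.0):
    return EffectTestRecord(kind, loci, ghat, 1.0 - moe, moe, log_bf)


def toy_truth():
    # causative = snp2 at 200 kbp on chromosome 1
    return {
        "causative_ids": ["snp2"],
        "causative_bp": np.array([200_000]),
        "causative_chrom": np.array([1]),
        "additive_effects": np.array([1.0]),
        "dominance_effects": np.array([0.0]),
    }


def toy_map():
    return pd.DataFrame(
        {
            "id": [f"snp{j}" for j in range(5)],
            "chrom": 1,
            "cM": np.arange(5.0),
            "bp": [0, 50_000, 200_000, 400_000, 600_000],
        }
    )


def test_hand_enumerated_windows():
    snp_map = toy_map()
    truth = toy_truth()
    # significant SNP at 400 kbp: 200 kbp away -> false positive
    fp = score_detection([rec("additive", (3,), 0.01)], snp_map, truth, alpha=0.05)
    assert fp.sensitivity["overall"] == 0.0
    assert fp.n_false_positive == 1
    assert fp.specificity == pytest.approx(1.0 - 1.0 / 1.0)
    # significant SNP at the causative itself -> true positive
    tp = score_detection(
        [rec("additive", (2,), 0.01), rec("additive", (1,), 0.5)], snp_map, truth, alpha=0.05
    )
    assert tp.sensitivity["additive"] == 1.0
    assert tp.sensitivity["overall"] == 1.0
    assert tp.n_false_positive == 0
    # SNP at 50 kbp sits 150 kbp away: outside the 100-kbp window
    near_miss = score_detection([rec("additive", (1,), 0.01)], snp_map, truth, alpha=0.05)
    assert near_miss.sensitivity["overall"] == 0.0
    assert near_miss.n_false_positive == 1


def test_all_nonsignificant_and_perfect_sets():
    snp_map = toy_map()
    truth = toy_truth()
    records = [rec("additive", (j,), 1.0, ghat=0.0) for j in range(5)]
    out = score_detection(records, snp_map, truth, alpha=0.05)
    assert out.sensitivity["overall"] == 0.0
    assert out.specificity == 1.0
    exact = [rec("additive", (j,), 0.01 if j == 2 else 1.0) for j in range(5)]
    out2 = score_detection(exact, snp_map, truth, alpha=0.05)
    assert out2.sensitivity["overall"] == 1.0
    assert out2.specificity == 1.0


def test_sensitivity_nested_in_alpha():
    snp_map = toy_map()
    truth = toy_truth()
    records = [rec("additive", (2,), 0.15)]
    s_small = score_detection(records, snp_map, truth, alpha=0.01).sensitivity["overall"]
    s_large = score_detection(records, snp_map, truth, alpha=0.20).sensitivity["overall"]
    assert s_small <= s_large
    assert s_large == 1.0


def test_epistatic_pair_matching_requires_kind():
    snp_map = toy_map()
    truth = toy_truth()
    truth["epistasis_pairs"] = {"epi_aa": [("snp2", "snp2", 0.5)], "epi_dd": []}
    hit = score_detection([rec("epi_aa", (2, 2), 0.01)], snp_map, truth, alpha=0.05)
    assert hit.sensitivity["epistasis"] == 1.0
    # a dd detection near an aa-interacting pair is a false positive
    miss = score_detection([rec("epi_dd", (2, 2), 0.01)], snp_map, truth, alpha=0.05)
    assert miss.sensitivity["epistasis"] == 0.0
    assert miss.n_false_positive == 1


def test_missing_truth_rejected():
    with pytest.raises(ValueError):
        score_detection([], toy_map(), {"causative_ids": []})


def test_explained_variance(rng):
    codes = random_codes(rng, 300, 5)
    table = make_table(codes)
    x2 = additive_values(codes[:, 2], table.maf[2])
    g_true = 1.4 * x2
    none = explained_variance([rec("additive", (2,), 1.0)], table, g_true)
    assert none == 0.0
    perfect = explained_variance([rec("additive", (2,), 0.01, ghat=1.4)], table, g_true)
    assert perfect == pytest.approx(1.0, abs=1e-12)
    over = explained_variance([rec("additive", (2,), 0.01, ghat=2.8)], table, g_true)
    assert over == pytest.approx(4.0, abs=1e-12)  # overestimation is not capped
    with pytest.raises(ValueError):
        explained_variance([], table, np.zeros(300))


def make_fit(table, ghat_vec):
    model = ModelSpec(kinds=("additive",))
    return FitResult(
        effects={"additive": np.asarray(ghat_vec, dtype=float)},
        fixed=None,
        sigma_e2=1.0,
        sweeps_run=1,
        converged=True,
        residual=np.zeros(table.n),
        model=model,
        priors={"main": PriorSpec(0.5, 1.0)},
    )


def test_prediction_accuracy(rng):
    codes = random_codes(rng, 150, 4)
    table = make_table(codes)
    beta = np.array([0.5, 0.0, -1.0, 0.2])
    X = np.column_stack([additive_values(codes[:, j], table.maf[j]) for j in range(4)])
    g_true = X @ beta
    assert prediction_accuracy(make_fit(table, beta), table, g_true) == pytest.approx(1.0)
    assert prediction_accuracy(make_fit(table, -beta), table, g_true) == pytest.approx(-1.0)
    with pytest.warns(UserWarning, match="zero-variance"):
        assert prediction_accuracy(make_fit(table, np.zeros(4)), table, g_true) == 0.0


def test_tune_gamma_degenerate_grid(rng):
    codes = random_codes(rng, 60, 8)
    table = make_table(codes)
    y = rng.normal(size=60)
    with pytest.warns(UserWarning):
        best, acc = tune_gamma(table, y, gamma_grid=(0.01,), split_seed=1)
    assert best == 0.01
    assert len(acc) == 1


def test_tune_gamma_pure_noise_warns_flat(rng):
    codes = random_codes(rng, 120, 10)
    table = make_table(codes)
    y = rng.normal(size=120)
    with pytest.warns(UserWarning, match="flat"):
        best, acc = tune_gamma(table, y, gamma_grid=(0.001, 0.01, 0.1), split_seed=2)
    assert best in (0.001, 0.01, 0.1)
    assert np.abs(acc["accuracy"]).max() < 0.5


def test_tune_gamma_prefers_informative_setting(rng):
    codes = random_codes(rng, 400, 30)
    table = make_table(codes)
    X = np.column_stack([additive_values(codes[:, j], table.maf[j]) for j in range(3)])
    y = X @ np.array([1.0, -0.8, 0.6]) + rng.normal(0, 1.0, 400)
    best, acc = tune_gamma(table, y, gamma_grid=(0.001, 0.01, 0.1), split_seed=3)
    assert acc["accuracy"].max() >= acc["accuracy"].min()
    assert best == float(acc.loc[acc["accuracy"].idxmax(), "gamma"])
    with pytest.raises(ValueError):
        tune_gamma(make_table(codes[:2]), y[:2], gamma_grid=(0.01,))
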