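import math

import numpy as np
import pandas as pd
import pytest

from malonmap.differential import (
    NS,
    Thresholds,
    assign_q_group,
    call_regulation,
    cv_statistic,
    differential_table,
    fold_change,
    heatmap_filter,
    t_test,
    top_n_sites,
)

A = ["SA1", "SA2"]
B = ["C1", "C2"]


def _matrix(rows):
    return pd.DataFrame.from_dict(rows, orient="index", columns=A + B)


def test_fold_change_is_ratio_of_group_means():
    R = _matrix({"s1": [10, 20, 5, 5], "s2": [3, 3, 3, 3]})
    fc = fold_change(R, A, B)
    assert fc["s1"] == pytest.approx(3.0)
    assert fc["s2"] == pytest.approx(1.0)


def test_fold_change_matches_brute_force_on_random_matrix():
    rng = np.random.default_rng(0)
    R = pd.DataFrame(rng.lognormal(0, 1, (20, 4)),
                     index=[f"s{i}" for i in range(20)], columns=A + B)
    fc = fold_change(R, A, B)
    for site in R.index:  # independent two-loop recomputation
        num = sum(R.loc[site, s] for s in A) / len(A)
        den = sum(R.loc[site, s] for s in B) / len(B)
        assert fc[site] == pytest.approx(num / den, rel=1e-12)


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ([2.0, 2.0], [1.0, 1.0], 0.0),                    # identical ratios
        ([1.0, 3.0], [1.0, 1.0], math.sqrt(2) / 2),       # ratios [1, 3]
        ([4.0, 6.0], [2.0, 2.0], (1 / math.sqrt(2)) / 2.5),  # ratios [2, 3]
    ],
)
def test_cv_is_sample_sd_over_mean_of_paired_ratios(a, b, expected):
    R = _matrix({"s": a + b})
    cv, n_pairs = cv_statistic(R, A, B)
    assert cv["s"] == pytest.approx(expected, abs=1e-9)
    assert n_pairs["s"] == 2


def test_cv_undefined_below_two_complete_pairs():
    R = _matrix({"s": [2.0, np.nan, 1.0, 1.0]})
    cv, n_pairs = cv_statistic(R, A, B)
    assert np.isnan(cv["s"]) and n_pairs["s"] == 1


def test_cv_invariant_to_common_rescaling_of_both_groups():
    rng = np.random.default_rng(5)
    vals = rng.lognormal(0, 0.3, 4)
    for c in (0.1, 3.0, 250.0):
        base, _ = cv_statistic(_matrix({"s": list(vals)}), A, B)
        scaled, _ = cv_statistic(_matrix({"s": list(vals * c)}), A, B)
        assert scaled["s"] == pytest.approx(base["s"], rel=1e-9)


def test_t_test_undefined_for_duplicate_designs():
    p = t_test(_matrix({"s": [2.0, 2.1, 1.0, 1.1]}), A, B)
    assert np.isnan(p["s"])


def test_t_test_degenerate_equal_groups_give_p_one():
    cols = ["SA1", "SA2", "SA3", "C1", "C2", "C3"]
    R = pd.DataFrame([[1.0] * 6], index=["s"], columns=cols)
    p = t_test(R, cols[:3], cols[3:])
    assert p["s"] == 1.0


def test_t_test_detects_planted_two_log2_unit_shift():
    """A 2-log2-unit shift at sigma = 0.1 with n = 3 per group is called at
    p < 0.05 in virtually every simulated site."""
    rng = np.random.default_rng(42)
    n = 500
    a_cols = ["SA1", "SA2", "SA3"]
    b_cols = ["C1", "C2", "C3"]
    a_vals = 2 ** (2.0 + rng.normal(0, 0.1, (n, 3)))
    b_vals = 2 ** rng.normal(0, 0.1, (n, 3))
    R = pd.DataFrame(np.hstack([a_vals, b_vals]),
                     index=[f"s{i}" for i in range(n)], columns=a_cols + b_cols)
    p = t_test(R, a_cols, b_cols)
    assert (p < 0.05).mean() >= 0.99


@pytest.mark.parametrize(
    "fc, cv, p, expected",
    [
        (1.6, 0.05, np.nan, "UP"),
        (0.5, 0.05, np.nan, "DOWN"),
        (1.6, 0.5, np.nan, "NS"),     # irreproducible replicates
        (1.5, 0.05, np.nan, "NS"),    # threshold itself is not regulation
        (1 / 1.5, 0.05, np.nan, "NS"),
        (1.6, 0.5, 0.01, "UP"),       # p-value takes precedence over CV
        (1.6, 0.05, 0.2, "NS"),
        (1.2, 0.05, np.nan, "NS"),    # significant but small effect
        (np.nan, 0.05, np.nan, "NS"),
    ],
)
def test_regulation_call_thresholds(fc, cv, p, expected):
    assert call_regulation(fc, cv, p, Thresholds()) == expected


@pytest.mark.parametrize(
    "fc, regulation, expected",
    [
        (0.4, "DOWN", "Q1"),
        (0.5, "DOWN", "Q1"),
        (0.55, "DOWN", "Q2"),
        (1.8, "UP", "Q3"),
        (2.0, "UP", "Q3"),
        (3.0, "UP", "Q4"),
        (1.2, "NS", "NONE"),
    ],
)
def test_q_group_bins(fc, regulation, expected):
    assert assign_q_group(fc, regulation) == expected


def test_fold_change_antisymmetry_on_complete_data():
    rng = np.random.default_rng(1)
    R = pd.DataFrame(rng.lognormal(0, 1, (100, 4)), columns=A + B)
    prod = fold_change(R, A, B) * fold_change(R, B, A)
    np.testing.assert_allclose(prod, 1.0, rtol=1e-12)


def test_group_swap_maps_up_to_down_and_mirrors_q_bins():
    rng = np.random.default_rng(2)
    vals = np.hstack([rng.lognormal(1.2, 0.05, (50, 2)),
                      rng.lognormal(0, 0.05, (50, 2))])
    R = pd.DataFrame(vals, index=[f"s{i}" for i in range(50)], columns=A + B)
    fwd = differential_table(R, A, B)
    rev = differential_table(R, B, A)
    swap = {"UP": "DOWN", "DOWN": "UP", "NS": "NS"}
    mirror = {"Q1": "Q4", "Q2": "Q3", "Q3": "Q2", "Q4": "Q1", "NONE": "NONE"}
    assert list(rev["regulation"]) == [swap[r] for r in fwd["regulation"]]
    assert list(rev["q_group"]) == [mirror[q] for q in fwd["q_group"]]


def test_heatmap_filter_requires_two_thirds_quantified():
    records = pd.DataFrame(
        {"fc": [2.0, 2.0, 2.0], "cv": 0.01, "p_value": np.nan,
         "regulation": "UP", "q_group": "Q3"},
        index=["full", "three", "two"],
    )
    R = pd.DataFrame(
        [[1, 1, 1, 1], [1, 1, 1, np.nan], [1, 1, np.nan, np.nan]],
        index=records.index, columns=A + B, dtype=float,
    )
    assert heatmap_filter(records, R) == ["full", "three"]


def test_top_sites_ranked_by_log2_magnitude_with_cv_ties():
    records = pd.DataFrame(
        {
            "fc": [4.0, 0.2, 1.6, 0.25, 4.0],
            "cv": [0.05, 0.03, 0.01, 0.08, 0.02],
        },
        index=["a", "b", "c", "d", "e"],
    )
    # |log2 fc|: a=2, b=2.32, c=0.678, d=2, e=2; ties a/d/e -> cv then id
    assert top_n_sites(records, 2) == ["b", "e"]
    assert top_n_sites(records, 10) == ["b", "e", "a", "d", "c"]


def test_planted_regulation_recovered_on_one_simulated_dataset():
    from malonmap.quantify import centralize, correct_by_protein
    from malonmap.synthetic_data import SimulationConfig, simulate

    bundle = simulate(SimulationConfig(seed=19, n_proteins=100, n_sites=600,
                                       true_fc_range=(3.0, 3.0),
                                       missing_rate=0.0))
    table = bundle.site_table
    R = correct_by_protein(centralize(table),
                           centralize(bundle.protein_table), table)
    records = differential_table(R, table.samples_in_group("SA"),
                                 table.samples_in_group("C"), table)
    merged = records.join(bundle.truth_sites["true_regulation"])
    planted = merged[merged["true_regulation"] != NS]
    called = merged[merged["regulation"] != NS]
    assert (planted["regulation"] == planted["true_regulation"]).mean() >= 0.95
    assert (called["regulation"] != called["true_regulation"]).mean() <= 0.05
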