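import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from malonmap.enrichment import (
    category_summary,
    fisher_enrich,
    fisher_two_sided,
    q_group_enrichment,
)


def enumeration_oracle(k, n, K, N):
    """Exact two-sided p by summing hypergeometric table counts whose
    probability does not exceed the observed table's (integer arithmetic)."""
    lo, hi = max(0, n + K - N), min(n, K)
    nums = [math.comb(K, x) * math.comb(N - K, n - x) for x in range(lo, hi + 1)]
    obs = nums[k - lo]
    return sum(v for v in nums if v <= obs) / math.comb(N, n)


def test_fisher_p_matches_enumeration_on_reference_table():
    assert fisher_two_sided(5, 10, 10, 100) == pytest.approx(
        enumeration_oracle(5, 10, 10, 100), abs=1e-12
    )


def test_fisher_equal_proportions_give_p_one():
    # k/n = K/N: the observed table is modal, every table contributes
    assert fisher_two_sided(1, 10, 10, 100) == pytest.approx(1.0)


def test_fisher_agrees_with_scipy_on_random_tables():
    rng = np.random.default_rng(8)
    for _ in range(300):
        N = int(rng.integers(2, 200))
        n = int(rng.integers(1, N + 1))
        K = int(rng.integers(1, N + 1))
        lo, hi = max(0, n + K - N), min(n, K)
        k = int(rng.integers(lo, hi + 1))
        table = [[k, n - k], [K - k, N - n - K + k]]
        assert fisher_two_sided(k, n, K, N) == pytest.approx(
            fisher_exact(table)[1], rel=1e-8, abs=1e-12
        )


ANN = pd.DataFrame(
    {
        "protein_id": [f"p{i}" for i in range(10)] + ["p0", "p1"],
        "namespace": ["KEGG"] * 10 + ["GO-BP"] * 2,
        "term_id": ["T1"] * 5 + ["T2"] * 5 + ["G1"] * 2,
        "term_name": ["t1"] * 5 + ["t2"] * 5 + ["g1"] * 2,
    }
)


def test_fisher_enrich_counts_and_skips_termless_sets():
    background = {f"p{i}" for i in range(20)}
    diff = {"p0", "p1", "p2", "p10"}
    res = fisher_enrich(diff, background, ANN, "KEGG")
    t1 = res[res.term_id == "T1"].iloc[0]
    assert (t1.k, t1.n, t1.K, t1.N) == (3, 4, 5, 20)
    assert t1.fold_enrichment == pytest.approx((3 / 4) / (5 / 20))
    # T2 (p5..p9) has no differential carrier -> skipped
    assert "T2" not in set(res.term_id)


def test_fisher_enrich_requires_diff_subset_of_background():
    with pytest.raises(ValueError, match="subset"):
        fisher_enrich({"x"}, {"y"}, ANN, "KEGG")


def test_bh_adjustment_preserves_p_value_order():
    rng = np.random.default_rng(3)
    prots = [f"p{i}" for i in range(200)]
    rows = []
    for t in range(15):
        carriers = rng.choice(prots, size=rng.integers(10, 60), replace=False)
        rows += [(p, "KEGG", f"T{t}", f"t{t}") for p in carriers]
    ann = pd.DataFrame(rows, columns=["protein_id", "namespace", "term_id",
                                      "term_name"])
    diff = set(rng.choice(prots, size=40, replace=False))
    res = fisher_enrich(diff, set(prots), ann, "KEGG")
    by_p = res.sort_values(["p_value", "term_id"])["term_id"]
    by_adj = res.sort_values(["p_adj", "p_value", "term_id"])["term_id"]
    assert list(by_p) == list(by_adj)


def test_label_permutation_destroys_enrichment():
    """After uniform relabeling the raw-p false-positive rate stays at or
    below the nominal 5% (the discrete Fisher test is conservative)."""
    rng = np.random.default_rng(12)
    prots = [f"p{i}" for i in range(300)]
    rows = []
    for t in range(20):
        carriers = rng.choice(prots, size=60, replace=False)
        rows += [(p, "KEGG", f"T{t}", f"t{t}") for p in carriers]
    ann = pd.DataFrame(rows, columns=["protein_id", "namespace", "term_id",
                                      "term_name"])
    hits = 0
    tests = 0
    for _ in range(200):
        diff = set(rng.choice(prots, size=40, replace=False))
        res = fisher_enrich(diff, set(prots), ann, "KEGG")
        hits += int((res.p_value < 0.05).sum())
        tests += len(res)
    rate = hits / tests
    se = math.sqrt(0.05 * 0.95 / tests)
    assert rate <= 0.05 + 2 * se


def test_planted_category_tops_its_q_group():
    rng = np.random.default_rng(4)
    prots = [f"p{i}" for i in range(200)]
    q1 = prots[:25]
    records = pd.DataFrame(
        {
            "protein_id": prots,
            "q_group": ["Q1"] * 25 + ["NONE"] * 175,
            "regulation": ["DOWN"] * 25 + ["NS"] * 175,
        },
        index=[f"{p}_K1" for p in prots],
    )
    rows = []
    for p in prots:
        if rng.random() < (0.8 if p in set(q1) else 0.1):
            rows.append((p, "KEGG", "PLANT", "planted term"))
        if rng.random() < 0.1:
            rows.append((p, "KEGG", "OTHER", "filler term"))
    ann = pd.DataFrame(rows, columns=["protein_id", "namespace", "term_id",
                                      "term_name"])
    mat = q_group_enrichment(records, ann, "KEGG")
    q1_col = mat.matrix["Q1"].dropna()
    assert q1_col.idxmax() == "PLANT"
    long_q1 = mat.long[mat.long.group == "Q1"]
    assert bool(long_q1.loc[long_q1.term_id == "PLANT", "significant"].iloc[0])


def test_q_group_matrix_degenerate_shapes():
    records = pd.DataFrame(
        {
            "protein_id": ["a", "b", "c", "d"],
            "q_group": ["Q1", "Q1", "NONE", "NONE"],
            "regulation": ["DOWN", "DOWN", "NS", "NS"],
        },
        index=["a_K1", "b_K1", "c_K1", "d_K1"],
    )
    ann = pd.DataFrame(
        {
            "protein_id": ["a", "b"],
            "namespace": "KEGG",
            "term_id": "T",
            "term_name": "t",
        }
    )
    mat = q_group_enrichment(records, ann, "KEGG")
    assert list(mat.matrix.columns) == ["Q1"]
    assert mat.col_order == ["Q1"]
    # identical duplicated groups give identical columns
    records2 = records.copy()
    records2.loc["c_K1", ["q_group", "regulation"]] = ["Q4", "UP"]
    records2.loc["d_K1", ["q_group", "regulation"]] = ["Q4", "UP"]
    ann2 = pd.concat(
        [ann, ann.assign(protein_id=["c", "d"])], ignore_index=True
    )
    mat2 = q_group_enrichment(records2, ann2, "KEGG")
    np.testing.assert_allclose(mat2.matrix["Q1"], mat2.matrix["Q4"])


def test_category_summary_multilabel_percentages():
    prots = [f"p{i}" for i in range(10)]
    rows = [(p, "COMPARTMENT", "cyto", "cytoplasm") for p in prots[:5]]
    rows += [(p, "COMPARTMENT", "ext", "extracellular") for p in prots[:2]]
    ann = pd.DataFrame(rows, columns=["protein_id", "namespace", "term_id",
                                      "term_name"])
    out = category_summary(prots, ann, "COMPARTMENT")
    cyto = out[out.term_id == "cyto"].iloc[0]
    assert (cyto["count"], cyto["percent"]) == (5, 50.0)
    assert out["count"].sum() == 7  # multi-label counting may exceed n proteins
    assert len(category_summary([], ann, "COMPARTMENT")) == 0
    assert len(category_summary(prots, ann.iloc[:0], "COMPARTMENT")) == 0
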