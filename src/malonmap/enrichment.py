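"""Fisher-exact functional enrichment of differential proteins.

Each annotation term is tested with a two-sided Fisher exact test on the
2x2 table (k, n-k; K-k, N-n-K+k), where k of the n differential proteins
and K of the N background proteins carry the term. Two-sidedness follows
the minimum-likelihood convention: the p-value sums the probabilities of
all tables with the observed margins whose probability does not exceed
that of the observed table. Benjamini-Hochberg adjusted p-values are
reported alongside, but the significance flag uses the raw p < alpha.

Per fold-change group (Q1..Q4) the significant terms are assembled into a
-log10(p) matrix and ordered by average-linkage hierarchical clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

#: relative tolerance when comparing table probabilities (guards float
#: round-off in the minimum-likelihood summation)
_PMF_RTOL = 1e-7


def fisher_two_sided(k: int, n: int, K: int, N: int) -> float:
    """Two-sided Fisher exact p for the table (k, n-k; K-k, N-n-K+k).

    Computed by summing hypergeometric probabilities over the support of
    tables with the observed margins whose probability is <= that of the
    observed table (minimum-likelihood method). Vectorizing over the whole
    support makes the test orders of magnitude faster than per-table calls
    when sweeping many tables with shared margins.
    """
    if not (0 <= k <= min(n, K)) or k < n + K - N:
        raise ValueError(f"impossible table: k={k}, n={n}, K={K}, N={N}")
    lo = max(0, n + K - N)
    hi = min(n, K)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, N, K, n)
    p_obs = pmf[k - lo]
    p = pmf[pmf <= p_obs * (1 + _PMF_RTOL)].sum()
    return float(min(p, 1.0))


@dataclass
class EnrichmentMatrix:
    """Clustered -log10(p) matrix of terms x groups."""

    matrix: pd.DataFrame  # term_id x group, nan where term untested
    row_order: list[str]
    col_order: list[str]
    long: pd.DataFrame  # concatenated per-group enrichment tables

    @property
    def ordered(self) -> pd.DataFrame:
        return self.matrix.loc[self.row_order, self.col_order]


def fisher_enrich(
    diff_proteins: set[str] | list[str],
    background_proteins: set[str] | list[str],
    annotations: pd.DataFrame,
    namespace: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term enrichment of a differential protein set against a background.

    The background is the universe of proteins eligible for the test
    (by default, in the pipeline, all proteins bearing quantified
    modification sites); ``diff_proteins`` must be a subset of it. Terms
    with no differential carrier (k = 0) are skipped.
    """
    diff = set(diff_proteins)
    background = set(background_proteins)
    if not diff <= background:
        raise ValueError("differential proteins must be a subset of the background")
    ann = annotations[annotations["namespace"] == namespace]
    ann = ann[ann["protein_id"].isin(background)]
    n, N = len(diff), len(background)
    rows = []
    for (term_id, term_name), grp in ann.groupby(["term_id", "term_name"], sort=True):
        carriers = set(grp["protein_id"])
        k = len(carriers & diff)
        if k < 1:
            continue
        K = len(carriers)
        p = fisher_two_sided(k, n, K, N)
        fold = (k / n) / (K / N)
        rows.append(
            {
                "namespace": namespace, "term_id": term_id, "term_name": term_name,
                "k": k, "n": n, "K": K, "N": N,
                "p_value": p, "fold_enrichment": fold,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "namespace", "term_id", "term_name", "k", "n", "K", "N",
            "p_value", "fold_enrichment",
        ],
    )
    if len(out):
        out["p_adj"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["significant"] = out["p_value"] < alpha
        out = out.sort_values(["p_value", "term_id"]).reset_index(drop=True)
    else:
        out["p_adj"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


def q_group_enrichment(
    records: pd.DataFrame,
    annotations: pd.DataFrame,
    namespace: str,
    background_proteins: set[str] | None = None,
    alpha: float = 0.05,
) -> EnrichmentMatrix:
    """Enrichment per fold-change group, clustered over significant terms.

    ``records`` is a differential table carrying ``protein_id`` and
    ``q_group``. The matrix holds -log10(raw p) over the union of terms
    significant in at least one group; missing cells (term untested in a
    group) stay nan and count as 0 only for clustering distances. Leaf
    order is deterministic.
    """
    if "protein_id" not in records.columns:
        raise ValueError("records must carry a protein_id column")
    if background_proteins is None:
        background_proteins = set(records["protein_id"].dropna())
    groups = sorted(g for g in records["q_group"].unique() if g != "NONE")
    per_group: dict[str, pd.DataFrame] = {}
    for g in groups:
        prots = set(records.loc[records["q_group"] == g, "protein_id"].dropna())
        res = fisher_enrich(prots, background_proteins, annotations, namespace, alpha)
        res.insert(0, "group", g)
        per_group[g] = res
    nonempty = [res for res in per_group.values() if len(res)]
    long = (
        pd.concat(nonempty, ignore_index=True)
        if nonempty
        else pd.DataFrame(
            columns=["group", "namespace", "term_id", "term_name", "k", "n",
                     "K", "N", "p_value", "fold_enrichment", "p_adj",
                     "significant"]
        )
    )
    terms = sorted(
        set().union(
            *(set(res.loc[res["significant"], "term_id"]) for res in per_group.values())
        )
    ) if per_group else []
    matrix = pd.DataFrame(np.nan, index=pd.Index(terms, name="term_id"), columns=groups)
    for g, res in per_group.items():
        hits = res[res["term_id"].isin(terms)]
        matrix.loc[hits["term_id"].to_numpy(), g] = -np.log10(
            hits["p_value"].to_numpy()
        )
    row_order = _cluster_order(matrix.fillna(0.0).to_numpy())
    col_order = _cluster_order(matrix.fillna(0.0).to_numpy().T)
    return EnrichmentMatrix(
        matrix=matrix,
        row_order=[terms[i] for i in row_order],
        col_order=[groups[i] for i in col_order],
        long=long,
    )


def _cluster_order(X: np.ndarray) -> list[int]:
    """Average-linkage / Euclidean leaf order; trivial for < 2 rows."""
    if X.shape[0] < 2:
        return list(range(X.shape[0]))
    if X.shape[0] == 2:
        return [0, 1]
    Z = hierarchy.linkage(X, method="average", metric="euclidean")
    return list(hierarchy.leaves_list(Z))


def category_summary(
    proteins: set[str] | list[str],
    annotations: pd.DataFrame,
    namespace: str,
) -> pd.DataFrame:
    """Counts and percentages of proteins per term (multi-label).

    A protein annotated to several terms counts once per term, so the
    percentages may sum past 100. Percentages are relative to the size of
    the supplied protein set.
    """
    proteins = set(proteins)
    ann = annotations[
        (annotations["namespace"] == namespace)
        & annotations["protein_id"].isin(proteins)
    ]
    if not len(proteins) or not len(ann):
        return pd.DataFrame(columns=["term_id", "term_name", "count", "percent"])
    out = (
        ann.groupby(["term_id", "term_name"])["protein_id"]
        .nunique()
        .rename("count")
        .reset_index()
    )
    out["percent"] = 100.0 * out["count"] / len(proteins)
    return out.sort_values(["count", "term_id"], ascending=[False, True]).reset_index(
        drop=True
    )
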