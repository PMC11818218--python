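"""Interaction-network views of differential proteins and dataset QC.

The network stage keeps high-confidence interactions (score above a
cutoff, 0.7 by default) among differential proteins and ranks proteins by
degree — "closest interactions" is read as highest connectivity. QC
summarizes per-sample log10 intensity distributions (box-plot statistics)
and runs a sample-level PCA on the complete-case relative-quant matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import SiteIntensityTable
from .quantify import RelativeQuantMatrix

log = logging.getLogger(__name__)


@dataclass
class NetworkView:
    """Degree-ranked high-confidence subnetwork of differential proteins.

    Node degrees are incident-edge counts within the view's own edge set,
    so the handshake identity (sum of degrees = 2 x edges) always holds.
    ``rank_degree`` is the degree in the full filtered differential graph
    that drove top-N selection.
    """

    nodes: pd.DataFrame  # protein_id index: degree, rank_degree, regulation
    edges: pd.DataFrame  # protein_a, protein_b, score


@dataclass
class QcSummary:
    sample_stats: pd.DataFrame  # per sample: count, min, q1, median, q3, max
    variance_explained: np.ndarray  # ordered fractions, sample-level PCA
    n_complete_sites: int


def build_network(
    edges: pd.DataFrame,
    records: pd.DataFrame,
    score_min: float = 0.7,
    top_n: int = 50,
) -> NetworkView:
    """High-confidence subnetwork of differential proteins.

    Edges with score <= ``score_min`` are dropped, both endpoints must be
    differential (regulation != NS), and the ``top_n`` proteins by degree
    are retained (ties by higher degree then lexicographic id).
    """
    diff = records[records["regulation"] != "NS"]
    if "protein_id" in diff.columns:
        diff_proteins = set(diff["protein_id"].dropna())
        reg_by_protein = (
            diff.groupby("protein_id")["regulation"].agg(lambda s: s.iloc[0]).to_dict()
        )
    else:  # records indexed directly by protein
        diff_proteins = set(diff.index)
        reg_by_protein = diff["regulation"].to_dict()

    kept = edges[
        (edges["score"] > score_min)
        & edges["protein_a"].isin(diff_proteins)
        & edges["protein_b"].isin(diff_proteins)
    ].copy()
    if not len(kept):
        log.warning("build_network: no edges pass the filters; empty network")
        nodes = pd.DataFrame(
            columns=["degree", "rank_degree", "regulation"],
            index=pd.Index([], name="protein_id"),
        )
        return NetworkView(nodes=nodes, edges=kept)

    G = nx.from_pandas_edgelist(kept, "protein_a", "protein_b", ["score"])
    degree = pd.Series(dict(G.degree()), name="rank_degree")
    order = degree.reset_index().sort_values(
        ["rank_degree", "index"], ascending=[False, True]
    )
    selected = list(order["index"][:top_n])
    sub_edges = kept[
        kept["protein_a"].isin(selected) & kept["protein_b"].isin(selected)
    ].reset_index(drop=True)
    counts = pd.concat([sub_edges["protein_a"], sub_edges["protein_b"]]).value_counts()
    nodes = pd.DataFrame(
        {
            "degree": [int(counts.get(p, 0)) for p in selected],
            "rank_degree": [int(degree[p]) for p in selected],
            "regulation": [reg_by_protein.get(p, "NS") for p in selected],
        },
        index=pd.Index(selected, name="protein_id"),
    )
    return NetworkView(nodes=nodes, edges=sub_edges)


def qc_report(
    R: RelativeQuantMatrix, raw: SiteIntensityTable
) -> QcSummary:
    """Per-sample intensity summaries and sample-level PCA.

    Box-plot statistics are computed on log10 raw intensities over the
    observed cells of each sample. PCA runs on the samples x sites matrix
    of relative values restricted to complete-case sites (no missing
    cell), column-centered; variance-explained fractions come from the
    singular values.
    """
    logI = np.log10(raw.intensities)
    stats = pd.DataFrame(
        {
            "count": logI.notna().sum(),
            "min": logI.min(),
            "q1": logI.quantile(0.25),
            "median": logI.median(),
            "q3": logI.quantile(0.75),
            "max": logI.max(),
        }
    )
    stats.index.name = "sample_id"

    values = R.values
    complete = values.dropna(axis=0, how="any")
    n_excluded = values.shape[0] - complete.shape[0]
    if n_excluded:
        log.info("qc_report: excluded %d site(s) with missing cells from PCA", n_excluded)
    fractions = pca_variance_fractions(complete.to_numpy(dtype=float).T)
    return QcSummary(
        sample_stats=stats,
        variance_explained=fractions,
        n_complete_sites=complete.shape[0],
    )


def pca_variance_fractions(X: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Ordered variance-explained fractions of a rows-as-observations matrix.

    Columns are mean-centered; fractions are squared singular values over
    their sum, truncated at numerical rank (at most n_observations - 1
    nonzero components).
    """
    if X.shape[0] < 2 or X.shape[1] == 0:
        return np.array([])
    Xc = X - X.mean(axis=0, keepdims=True)
    s = np.linalg.svd(Xc, compute_uv=False)
    total = (s**2).sum()
    if total <= tol:
        return np.zeros(min(X.shape[0] - 1, X.shape[1]))
    frac = (s**2) / total
    k = min(X.shape[0] - 1, X.shape[1])
    return frac[:k]
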