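"""Differential screening of modification sites.

For each site the screen computes the fold change (ratio of group means
of relative values, treatment over control), a reproducibility CV over
paired replicate ratios, and — when each group carries at least three
observations — a Welch t-test on log2 relative values. A site is called
significant when p < alpha if a p-value exists, otherwise when CV falls
below the reproducibility threshold (the duplicate-design criterion).
Significant sites with fold change above the up-threshold are UP, below
its reciprocal DOWN. Regulated sites are then binned into fold-change
groups Q1..Q4 for stratified enrichment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import RelativeQuantMatrix

log = logging.getLogger(__name__)

UP, DOWN, NS = "UP", "DOWN", "NS"
Q_NONE = "NONE"


@dataclass(frozen=True)
class Thresholds:
    """Screening thresholds.

    fc: regulation threshold on the fold change (UP above it, DOWN below
    its reciprocal, strict inequalities). cv: reproducibility ceiling used
    when no t-test p is available. alpha: significance level for the
    t-test. q_bins: (lo, mid_lo, mid_hi, hi) bounds such that
    Q1: fc <= lo, Q2: lo < fc < mid_lo, Q3: mid_hi < fc <= hi, Q4: fc > hi.
    """

    fc: float = 1.5
    cv: float = 0.1
    alpha: float = 0.05
    q_bins: tuple[float, float, float, float] = (0.5, 1 / 1.5, 1.5, 2.0)


def _group_values(R: RelativeQuantMatrix | pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    values = R.values if isinstance(R, RelativeQuantMatrix) else R
    missing = [s for s in samples if s not in values.columns]
    if missing:
        raise KeyError(f"samples not in matrix: {missing}")
    return values[samples]


def fold_change(
    R: RelativeQuantMatrix | pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
) -> pd.Series:
    """FC = mean(R over group A, observed) / mean(R over group B, observed).

    Sites with no observed value in either group get nan (excluded).
    """
    mean_a = _group_values(R, group_a).mean(axis=1, skipna=True)
    mean_b = _group_values(R, group_b).mean(axis=1, skipna=True)
    fc = mean_a / mean_b
    n_undef = int(fc.isna().sum())
    if n_undef:
        log.warning("fold_change: %d site(s) undefined (empty group)", n_undef)
    return fc


def cv_statistic(
    R: RelativeQuantMatrix | pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
) -> tuple[pd.Series, pd.Series]:
    """Coefficient of variation of paired replicate ratios.

    Replicate m of group A is paired with replicate m of group B in the
    supplied (file) order: ratios r_m = A_m / B_m over complete pairs, and
    CV = sample SD (n-1 denominator) of the ratios over their mean.
    Returns (cv, n_pairs); cv is nan where fewer than 2 complete pairs exist.
    """
    n_rep = min(len(group_a), len(group_b))
    a = _group_values(R, group_a[:n_rep]).to_numpy(dtype=float)
    b = _group_values(R, group_b[:n_rep]).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = a / b  # nan propagates from either side
        finite = np.isfinite(ratios)
        n_pairs = finite.sum(axis=1)
        r = np.where(finite, ratios, 0.0)
        denom = np.maximum(n_pairs, 1)
        mean_r = r.sum(axis=1) / denom
        ss = (np.where(finite, ratios - mean_r[:, None], 0.0) ** 2).sum(axis=1)
        sd_r = np.sqrt(ss / np.maximum(n_pairs - 1, 1))
        cv = np.where(n_pairs >= 2, sd_r / mean_r, np.nan)
    index = R.values.index if isinstance(R, RelativeQuantMatrix) else R.index
    return pd.Series(cv, index=index), pd.Series(n_pairs, index=index)


def t_test(
    R: RelativeQuantMatrix | pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    min_per_group: int = 3,
) -> pd.Series:
    """Two-sided Welch t-test on log2 relative values, per site.

    Undefined (nan) unless both groups carry at least ``min_per_group``
    observed values — duplicate designs skip the test and fall back to the
    CV criterion. Degenerate zero-variance sites give p = 1 when the group
    means are equal, else p = 0.
    """
    a = np.log2(_group_values(R, group_a).to_numpy(dtype=float))
    b = np.log2(_group_values(R, group_b).to_numpy(dtype=float))
    index = R.values.index if isinstance(R, RelativeQuantMatrix) else R.index
    p = np.full(len(index), np.nan)
    ok = (np.isfinite(a).sum(axis=1) >= min_per_group) & (
        np.isfinite(b).sum(axis=1) >= min_per_group
    )
    if ok.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(
                a[ok], b[ok], axis=1, equal_var=False, nan_policy="omit"
            )
        pv = np.asarray(res.pvalue, dtype=float)
        # zero within-group variance in both groups: t is 0/0
        degenerate = ~np.isfinite(pv)
        if degenerate.any():
            mean_a = np.nanmean(a[ok], axis=1)
            mean_b = np.nanmean(b[ok], axis=1)
            pv[degenerate] = np.where(
                np.isclose(mean_a, mean_b), 1.0, 0.0
            )[degenerate]
        p[ok] = pv
    return pd.Series(p, index=index)


def call_regulation(
    fc: float, cv: float, p: float, thresholds: Thresholds = Thresholds()
) -> str:
    """Classify one site as UP, DOWN or NS.

    Significance gate: p < alpha when a t-test p exists; otherwise
    CV < cv threshold. Fold-change comparisons are strict, so a fold
    change of exactly the threshold is NS.
    """
    if fc is None or not math.isfinite(fc):
        return NS
    has_p = p is not None and math.isfinite(p)
    has_cv = cv is not None and math.isfinite(cv)
    if has_p:
        significant = p < thresholds.alpha
    elif has_cv:
        significant = cv < thresholds.cv
    else:
        significant = False
    if not significant:
        return NS
    if fc > thresholds.fc:
        return UP
    if fc < 1 / thresholds.fc:
        return DOWN
    return NS


def assign_q_group(
    fc: float, regulation: str, thresholds: Thresholds = Thresholds()
) -> str:
    """Bin a regulated site by fold-change magnitude.

    Q1: fc <= lo; Q2: lo < fc < mid_lo; Q3: mid_hi < fc <= hi; Q4: fc > hi.
    Non-significant sites carry no bin.
    """
    if regulation == NS or fc is None or not math.isfinite(fc):
        return Q_NONE
    lo, mid_lo, mid_hi, hi = thresholds.q_bins
    if fc <= lo:
        return "Q1"
    if fc < mid_lo:
        return "Q2"
    if fc > hi:
        return "Q4"
    if fc > mid_hi:
        return "Q3"
    return Q_NONE


def differential_table(
    R: RelativeQuantMatrix | pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    site_table=None,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Full per-site differential screen.

    Returns a DataFrame indexed by site_id with columns ``fc``, ``cv``,
    ``p_value``, ``n_pairs``, ``regulation``, ``q_group`` (and
    ``protein_id`` when a site table is supplied). Sites with undefined
    fold change are dropped.
    """
    fc = fold_change(R, group_a, group_b)
    cv, n_pairs = cv_statistic(R, group_a, group_b)
    p = t_test(R, group_a, group_b)
    out = pd.DataFrame({"fc": fc, "cv": cv, "p_value": p, "n_pairs": n_pairs})
    out = out[np.isfinite(out["fc"])]
    out["regulation"] = [
        call_regulation(f, c, pv, thresholds)
        for f, c, pv in zip(out["fc"], out["cv"], out["p_value"])
    ]
    out["q_group"] = [
        assign_q_group(f, reg, thresholds)
        for f, reg in zip(out["fc"], out["regulation"])
    ]
    if site_table is not None:
        out["protein_id"] = site_table.sites["protein_id"].reindex(out.index)
    return out


def heatmap_filter(
    records: pd.DataFrame,
    R: RelativeQuantMatrix | pd.DataFrame,
    min_fraction: float = 2 / 3,
) -> list[str]:
    """Differential sites quantified in at least ``min_fraction`` of samples.

    A site passes when its observed-sample count is >= ceil(min_fraction x
    n_samples). Only regulated (non-NS) sites are considered.
    """
    values = R.values if isinstance(R, RelativeQuantMatrix) else R
    need = math.ceil(min_fraction * values.shape[1])
    diff_ids = records.index[records["regulation"] != NS]
    obs = values.reindex(diff_ids).notna().sum(axis=1)
    return list(obs.index[obs >= need])


def top_n_sites(records: pd.DataFrame, n: int = 30) -> list[str]:
    """The n most strongly differential sites.

    Ranked by |log2 fc| descending; ties broken by smaller CV (undefined
    CV ranks last) then lexicographic site id.
    """
    # stable sort on site_id first so equal (|log2 fc|, cv) break lexicographically
    df = (
        records.assign(_mag=np.abs(np.log2(records["fc"])),
                       _cv=records["cv"].fillna(np.inf))
        .sort_index()
        .sort_values(["_mag", "_cv"], ascending=[False, True], kind="mergesort")
    )
    return list(df.index[:n])
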