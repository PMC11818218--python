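"""Sequence-motif analysis around modified lysines.

Foreground windows are the +/-10-residue flanks of modified sites;
background windows flank every occurrence of the modifiable residue in
the proteome. Motifs are discovered motif-x style: greedily fix the
(offset, residue) pair with the smallest binomial tail probability
P(X >= k_fg) with X ~ Binomial(n_fg, f_bg), reduce foreground and
background to windows matching the partial motif, and repeat until no
pair clears the significance and occurrence thresholds; emit the motif,
remove its foreground windows from the pool, restore the full background
and restart. Terminal overhangs are padded with "_", which never counts
as a residue in any frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from .io_formats import SiteIntensityTable

log = logging.getLogger(__name__)

PAD = "_"
WINDOW_FLANK = 10
WINDOW_LEN = 2 * WINDOW_FLANK + 1
CENTER = WINDOW_FLANK  # index of the modified residue within a window

AA20 = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class FixedPosition:
    offset: int  # relative to the modified residue, never 0
    residue: str
    binomial_p: float
    fg_count: int  # foreground matches at the moment of fixing


@dataclass
class MotifResult:
    """One discovered motif.

    ``pattern`` uses the compact colon notation with the modified residue
    rendered as e.g. ``Kmal`` (so ``Kmal:::C`` places a C at offset +4);
    ``regex21`` is the full 21-slot dot-wildcard form.
    """

    pattern: str
    regex21: str
    fixed_positions: list[FixedPosition] = field(default_factory=list)
    fg_matches: int = 0
    bg_matches: int = 0
    fold_increase: float = float("nan")


def extract_window(seq: str, position: int) -> str:
    """21-mer around a 1-based position, padded with '_' past the termini."""
    i = position - 1
    left = seq[max(0, i - WINDOW_FLANK) : i]
    right = seq[i + 1 : i + 1 + WINDOW_FLANK]
    return (
        PAD * (WINDOW_FLANK - len(left))
        + left
        + seq[i]
        + right
        + PAD * (WINDOW_FLANK - len(right))
    )


def extract_windows(
    fasta_map: dict[str, str], sites: SiteIntensityTable | pd.DataFrame
) -> pd.DataFrame:
    """Foreground windows for modified sites.

    A site whose declared residue does not match the sequence at its
    position is skipped with a warning — this guards against off-by-one
    coordinate bugs upstream.
    """
    meta = sites.sites if isinstance(sites, SiteIntensityTable) else sites
    rows, skipped = [], 0
    for site_id, row in meta.iterrows():
        seq = fasta_map.get(row["protein_id"])
        pos = int(row["position"])
        if seq is None or pos > len(seq) or seq[pos - 1] != row["residue"]:
            skipped += 1
            continue
        rows.append({"site_id": site_id, "window": extract_window(seq, pos)})
    if skipped:
        log.warning("extract_windows: skipped %d site(s) with residue mismatch", skipped)
    return pd.DataFrame(rows, columns=["site_id", "window"])


def build_background(fasta_map: dict[str, str], residue: str = "K") -> list[str]:
    """One window per occurrence of ``residue`` in every protein."""
    windows = []
    for pid in fasta_map:
        seq = fasta_map[pid]
        for i, aa in enumerate(seq):
            if aa == residue:
                windows.append(extract_window(seq, i + 1))
    return windows


def binomial_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p)."""
    if k <= 0:
        return 1.0
    return float(binom.sf(k - 1, n, p))


def _char_matrix(windows) -> np.ndarray:
    if len(windows) == 0:
        return np.empty((0, WINDOW_LEN), dtype="<U1")
    return np.array([list(w) for w in windows], dtype="<U1")


_OFFSETS = [o for o in range(-WINDOW_FLANK, WINDOW_FLANK + 1) if o != 0]


def motif_discovery(
    fg_windows,
    bg_windows,
    p_threshold: float = 1e-6,
    min_occ: int = 20,
    center_label: str = "Kmal",
) -> list[MotifResult]:
    """Iterative greedy binomial motif extraction.

    Ties in the minimal binomial p are broken by smaller |offset|
    (upstream before downstream at equal distance), then alphabetical
    residue. Each foreground window is consumed by at most one motif.
    """
    fg_pool = _char_matrix(list(fg_windows))
    bg_all = _char_matrix(list(bg_windows))
    if bg_all.shape[0] == 0:
        raise ValueError("empty background window set")
    results: list[MotifResult] = []
    while fg_pool.shape[0] >= min_occ:
        fixed = _grow_motif(fg_pool, bg_all, p_threshold, min_occ)
        if not fixed:
            break
        fg_mask = _match_mask(fg_pool, fixed)
        bg_mask = _match_mask(bg_all, fixed)
        n_fg0, n_bg0 = fg_pool.shape[0], bg_all.shape[0]
        fg_matches = int(fg_mask.sum())
        bg_matches = int(bg_mask.sum())
        fg_frac = fg_matches / n_fg0
        bg_frac = bg_matches / n_bg0
        results.append(
            MotifResult(
                pattern=render_pattern(fixed, center_label),
                regex21=render_regex21(fixed),
                fixed_positions=fixed,
                fg_matches=fg_matches,
                bg_matches=bg_matches,
                fold_increase=fg_frac / bg_frac if bg_frac > 0 else float("inf"),
            )
        )
        fg_pool = fg_pool[~fg_mask]
    return results


def _grow_motif(
    fg: np.ndarray, bg: np.ndarray, p_threshold: float, min_occ: int
) -> list[FixedPosition]:
    fixed: list[FixedPosition] = []
    fg_cur, bg_cur = fg, bg
    taken: set[int] = set()
    while True:
        best = None  # (p, |offset|, offset, residue, k)
        for off in _OFFSETS:
            if off in taken:
                continue
            col = CENTER + off
            fg_col = fg_cur[:, col]
            bg_col = bg_cur[:, col]
            fg_valid = fg_col != PAD
            bg_valid = bg_col != PAD
            n_fg = int(fg_valid.sum())
            n_bg = int(bg_valid.sum())
            if n_fg == 0 or n_bg == 0:
                continue
            for aa in AA20:
                k = int((fg_col == aa).sum())
                if k < min_occ:
                    continue
                f_bg = float((bg_col == aa).sum()) / n_bg
                p = binomial_tail(k, n_fg, f_bg)
                if p >= p_threshold:
                    continue
                cand = (p, abs(off), off, aa, k)
                if best is None or cand < best:
                    best = cand
        if best is None:
            return fixed
        p, _, off, aa, k = best
        fixed.append(FixedPosition(offset=off, residue=aa, binomial_p=p, fg_count=k))
        taken.add(off)
        col = CENTER + off
        fg_cur = fg_cur[fg_cur[:, col] == aa]
        bg_cur = bg_cur[bg_cur[:, col] == aa]
        if fg_cur.shape[0] == 0:
            return fixed


def _match_mask(windows: np.ndarray, fixed: list[FixedPosition]) -> np.ndarray:
    mask = np.ones(windows.shape[0], dtype=bool)
    for fp in fixed:
        mask &= windows[:, CENTER + fp.offset] == fp.residue
    return mask


def render_regex21(fixed: list[FixedPosition]) -> str:
    slots = ["."] * WINDOW_LEN
    slots[CENTER] = "K"
    for fp in fixed:
        slots[CENTER + fp.offset] = fp.residue
    return "".join(slots)


def render_pattern(fixed: list[FixedPosition], center_label: str = "Kmal") -> str:
    """Compact colon notation: wildcards between the center and the
    outermost fixed residues render as ':', e.g. C at +4 -> 'Kmal:::C'."""
    offsets = [fp.offset for fp in fixed]
    lo = min([0] + offsets)
    hi = max([0] + offsets)
    by_offset = {fp.offset: fp.residue for fp in fixed}
    parts = []
    for off in range(lo, hi + 1):
        if off == 0:
            parts.append(center_label)
        else:
            parts.append(by_offset.get(off, ":"))
    return "".join(parts)


def frequency_heatmap(
    fg_windows, bg_windows, epsilon: float = 0.5
) -> pd.DataFrame:
    """Residue x offset log2 enrichment of foreground over background.

    Per (residue, offset) the entry is log2(f_fg / f_bg) where each
    relative frequency gets a pseudo-count of ``epsilon`` in the numerator
    and 20 * epsilon in the denominator, so entries stay finite and the map
    is exactly zero when foreground equals background. Pad characters are
    excluded from the denominators; the center column (offset 0) is not
    reported.
    """
    fg = _char_matrix(list(fg_windows))
    bg = _char_matrix(list(bg_windows))
    data = np.zeros((len(AA20), len(_OFFSETS)))
    for j, off in enumerate(_OFFSETS):
        col = CENTER + off
        fg_col = fg[:, col]
        bg_col = bg[:, col]
        n_fg = int((fg_col != PAD).sum())
        n_bg = int((bg_col != PAD).sum())
        for i, aa in enumerate(AA20):
            f_fg = (int((fg_col == aa).sum()) + epsilon) / (n_fg + epsilon * len(AA20))
            f_bg = (int((bg_col == aa).sum()) + epsilon) / (n_bg + epsilon * len(AA20))
            data[i, j] = np.log2(f_fg / f_bg)
    return pd.DataFrame(data, index=list(AA20), columns=_OFFSETS)


def motif_table(results: list[MotifResult]) -> pd.DataFrame:
    """Flatten motif results for TSV export."""
    rows = []
    for m in results:
        rows.append(
            {
                "pattern": m.pattern,
                "regex21": m.regex21,
                "n_fixed": len(m.fixed_positions),
                "fixed": ";".join(
                    f"{fp.offset:+d}{fp.residue}(p={fp.binomial_p:.3g})"
                    for fp in m.fixed_positions
                ),
                "fg_matches": m.fg_matches,
                "bg_matches": m.bg_matches,
                "fold_increase": m.fold_increase,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pattern", "regex21", "n_fixed", "fixed",
            "fg_matches", "bg_matches", "fold_increase",
        ],
    )
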