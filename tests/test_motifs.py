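from collections import Counter

import numpy as np
import pandas as pd
import pytest

from malonmap.motifs import (
    FixedPosition,
    binomial_tail,
    build_background,
    extract_window,
    extract_windows,
    frequency_heatmap,
    motif_discovery,
    render_pattern,
)

AA = list("ACDEFGHIKLMNPQRSTVWY")


def test_extract_window_pads_terminal_overhangs():
    seq = "MKACDEFGHIKLMNPQRSTVW"
    w = extract_window(seq, 2)
    assert w == "_________MKACDEFGHIKL"
    assert len(w) == 21 and w[10] == "K"
    # an interior site with >= 10 residues on both sides has no pads
    w2 = extract_window(seq, 11)
    assert w2 == seq[0:21] and "_" not in w2


def test_extract_windows_skips_residue_mismatches():
    sites = pd.DataFrame(
        {
            "protein_id": ["p1", "p1"],
            "position": [2, 3],
            "residue": ["K", "K"],  # position 3 is 'A' -> mismatch
            "localization_prob": 1.0,
        },
        index=["p1_K2", "p1_K3"],
    )
    out = extract_windows({"p1": "MKACDEFGHIKLMNPQRSTVW"}, sites)
    assert list(out.site_id) == ["p1_K2"]


def test_background_enumerates_every_lysine_and_contains_foreground(small_bundle):
    assert len(build_background({"p": "MKAKCK"})) == 3
    bg = set(build_background(small_bundle.fasta_map))
    fg = extract_windows(small_bundle.fasta_map, small_bundle.site_table)
    assert set(fg.window) <= bg


def test_binomial_tail_by_enumeration():
    # P(X >= 2 | n=3, p=0.5) = 3/8 + 1/8
    assert binomial_tail(2, 3, 0.5) == pytest.approx(0.5)
    assert binomial_tail(0, 3, 0.5) == 1.0


def _random_windows(rng, n, c_freq=0.02):
    probs = np.full(20, (1 - c_freq) / 19)
    probs[AA.index("C")] = c_freq
    flanks = rng.choice(AA, p=probs, size=(n, 21))
    flanks[:, 10] = "K"
    return ["".join(row) for row in flanks]


def test_no_motifs_when_foreground_matches_background():
    rng = np.random.default_rng(0)
    bg = _random_windows(rng, 3000)
    assert motif_discovery(bg, bg, 1e-6, 20) == []


def test_planted_motif_is_recovered_first():
    rng = np.random.default_rng(1)
    bg = _random_windows(rng, 3000)
    fg = [list(w) for w in rng.choice(bg, size=500, replace=False)]
    for row in fg[: int(0.6 * len(fg))]:
        row[12] = "C"  # offset +2
    fg = ["".join(row) for row in fg]
    found = motif_discovery(fg, bg, 1e-6, 20)
    assert found
    first = found[0].fixed_positions[0]
    assert (first.offset, first.residue) == (2, "C")
    assert found[0].pattern.startswith("Kmal:C") or found[0].pattern == "Kmal:C"


def test_motifs_respect_thresholds_and_consume_foreground_once():
    rng = np.random.default_rng(2)
    bg = _random_windows(rng, 4000)
    fg = [list(w) for w in rng.choice(bg, size=800, replace=False)]
    for row in fg[:400]:
        row[12] = "C"
    for row in fg[400:650]:
        row[8] = "H"  # second motif at offset -2
    fg = ["".join(row) for row in fg]
    found = motif_discovery(fg, bg, 1e-6, 20)
    assert len(found) >= 2
    for m in found:
        assert m.fg_matches >= 20
        for fp in m.fixed_positions:
            assert fp.binomial_p < 1e-6 and fp.fg_count >= 20
    assert sum(m.fg_matches for m in found) <= len(fg)


@pytest.mark.parametrize(
    "fixed, expected",
    [
        ([(4, "C")], "Kmal:::C"),
        ([(2, "C")], "Kmal:C"),
        ([(-2, "C")], "C:Kmal"),
        ([(10, "K")], "Kmal:::::::::K"),
        ([(-1, "A"), (3, "W")], "AKmal::W"),
        ([], "Kmal"),
    ],
)
def test_colon_pattern_rendering(fixed, expected):
    fps = [FixedPosition(o, r, 1e-9, 99) for o, r in fixed]
    assert render_pattern(fps) == expected


def test_frequency_heatmap_identity_and_depletion():
    rng = np.random.default_rng(3)
    bg = _random_windows(rng, 500)
    hm = frequency_heatmap(bg, bg)
    np.testing.assert_allclose(hm.to_numpy(), 0.0, atol=1e-12)
    # residue absent from the foreground stays finite but negative
    no_c = [w.replace("C", "A") for w in bg]
    hm2 = frequency_heatmap(no_c, bg)
    c_row = hm2.loc["C"]
    assert np.isfinite(c_row).all() and (c_row <= 0).all()


def test_frequency_heatmap_matches_direct_recount():
    rng = np.random.default_rng(4)
    fg = _random_windows(rng, 200, c_freq=0.1)
    bg = _random_windows(rng, 200, c_freq=0.02)
    hm = frequency_heatmap(fg, bg, epsilon=0.5)
    for off in (-10, -3, 1, 7):
        col = 10 + off
        fg_counts = Counter(w[col] for w in fg if w[col] != "_")
        bg_counts = Counter(w[col] for w in bg if w[col] != "_")
        n_fg, n_bg = sum(fg_counts.values()), sum(bg_counts.values())
        for aa in ("A", "C", "K"):
            f = (fg_counts[aa] + 0.5) / (n_fg + 10.0)
            b = (bg_counts[aa] + 0.5) / (n_bg + 10.0)
            assert hm.loc[aa, off] == pytest.approx(np.log2(f / b), rel=1e-12)


def test_empty_background_is_fatal():
    with pytest.raises(ValueError, match="background"):
        motif_discovery(["A" * 10 + "K" + "A" * 10], [], 1e-6, 1)
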