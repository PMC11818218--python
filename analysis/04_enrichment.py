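#!/usr/bin/env python
"""Fisher-exact functional enrichment per fold-change group.

For each Q-group's proteins (background = all proteins with quantified
sites) every annotation term is tested with the two-sided Fisher exact
test; significant terms (raw p < 0.05) form a -log10(p) matrix ordered by
average-linkage hierarchical clustering. Writes per-namespace long tables
and clustered matrices under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from malonmap.enrichment import q_group_enrichment
from malonmap.io_formats import read_annotation

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=ROOT / "results" / "sim")
    ap.add_argument("--diff", type=Path,
                    default=ROOT / "results" / "differential.tsv")
    ap.add_argument("--out-dir", type=Path, default=ROOT / "results")
    ap.add_argument("--namespaces", nargs="+",
                    default=["KEGG", "GO-BP", "DOMAIN"])
    args = ap.parse_args()

    records = pd.read_csv(args.diff, sep="\t", index_col=0)
    annotations = read_annotation(args.sim / "annotations.tsv")
    for ns in args.namespaces:
        mat = q_group_enrichment(records, annotations, ns)
        mat.long.to_csv(args.out_dir / f"enrichment_{ns}.tsv", sep="\t",
                        index=False, na_rep="NA", float_format="%.10g")
        mat.ordered.to_csv(args.out_dir / f"enrichment_matrix_{ns}.tsv",
                           sep="\t", na_rep="NA", float_format="%.10g")
        sig = mat.long[mat.long.significant]
        print(f"{ns}: {len(sig)} significant (group, term) pairs over "
              f"groups {list(mat.matrix.columns)}")
        for _, row in sig.nsmallest(3, "p_value").iterrows():
            print(f"  {row.group} {row.term_id} ({row.term_name}): "
                  f"p={row.p_value:.3g}, fold={row.fold_enrichment:.2f} "
                  f"[{row.k}/{row.n} vs {row.K}/{row.N}]")


if __name__ == "__main__":
    main()
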