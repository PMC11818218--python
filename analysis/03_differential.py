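#!/usr/bin/env python
"""Screen sites for differential malonylation and compare with the truth.

Computes fold change (SA over C), the paired-ratio CV, regulation calls
at fc > 1.5 / < 1/1.5 with CV < 0.1, and Q-group bins; applies the
2/3-completeness heatmap filter and picks the top-30 sites. Writes
results/differential.tsv, results/heatmap_matrix.tsv, results/top_sites.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd
import yaml

from malonmap.differential import differential_table, heatmap_filter, top_n_sites
from malonmap.io_formats import read_protein_table, read_site_table
from malonmap.quantify import centralize, correct_by_protein

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=ROOT / "results" / "sim")
    ap.add_argument("--out-dir", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    groups = yaml.safe_load((args.sim / "groups.yaml").read_text())["sample_groups"]
    sites = read_site_table(args.sim / "sites.tsv", groups)
    R = correct_by_protein(
        centralize(sites),
        centralize(read_protein_table(args.sim / "proteins.tsv")),
        sites,
    )
    records = differential_table(
        R, sites.samples_in_group("SA"), sites.samples_in_group("C"), sites
    )
    kept = heatmap_filter(records, R)
    top = top_n_sites(records[records.regulation != "NS"])

    args.out_dir.mkdir(parents=True, exist_ok=True)
    records.to_csv(args.out_dir / "differential.tsv", sep="\t", na_rep="NA",
                   float_format="%.10g")
    R.values.reindex(kept).to_csv(args.out_dir / "heatmap_matrix.tsv", sep="\t",
                                  na_rep="NA", float_format="%.10g")
    records.reindex(top).to_csv(args.out_dir / "top_sites.tsv", sep="\t",
                                na_rep="NA", float_format="%.10g")

    print(f"tested {len(records)} sites: "
          f"UP {(records.regulation == 'UP').sum()}, "
          f"DOWN {(records.regulation == 'DOWN').sum()}")
    print("Q-group counts:",
          records[records.q_group != "NONE"].q_group.value_counts().to_dict())
    print(f"heatmap filter kept {len(kept)} differential sites; "
          f"top-{len(top)} selected")

    truth_path = args.sim / "truth_sites.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t", index_col=0)
        merged = records.join(truth["true_regulation"])
        planted = merged[merged.true_regulation != "NS"]
        sens = (planted.regulation == planted.true_regulation).mean()
        called = merged[merged.regulation != "NS"]
        fdr = (called.regulation != called.true_regulation).mean()
        print(f"vs truth: sensitivity {sens:.3f}, FDR {fdr:.3f}")


if __name__ == "__main__":
    main()
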