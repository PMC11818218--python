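# malonmap

Differential analysis of lysine-malonylation (Kmal) sites from label-free
proteomics intensity tables.

Lysine malonylation is an acidic post-translational modification that flips
the side-chain charge of a lysine from +1 to −1. Quantitative Kmal studies —
for example comparing a stress treatment such as salicylic acid against a
control in plant tissue — produce a table of modification-site intensities
per sample plus a protein-level quantification table, and ask: *which sites
change in modification stoichiometry, what functions do the affected
proteins serve, and what sequence context surrounds the modified lysines?*
`malonmap` implements that screening pipeline as a tested library with a CLI,
together with a synthetic-data generator with planted ground truth so every
stage can be validated end to end without any external download.

## The method

For site *j* with intensity *I<sub>ij</sub>* in sample *i*:

1. **Centralization.** *R<sub>ij</sub> = I<sub>ij</sub> / mean<sub>i</sub>(I<sub>ij</sub>)*
   — each site's intensities are divided by that site's mean over its
   observed samples, giving relative values with mean 1.
2. **Protein correction.** *R<sub>ij</sub> ← R<sub>ij</sub> / R<sup>prot</sup><sub>ij</sub>*
   cell-wise against the parent protein's centralized values, removing
   protein-abundance effects so the remaining signal reflects modification
   stoichiometry. Cells without a protein value keep the raw relative value
   and are flagged.
3. **Differential screen.** Fold change *FC = mean(R, treatment) /
   mean(R, control)*; reproducibility *CV = SD(A₁/B₁, A₂/B₂, …) /
   mean(A₁/B₁, A₂/B₂, …)* over order-paired replicate ratios (sample SD,
   n−1); a Welch t-test on log2 R when each group has ≥ 3 observations.
   A site is significant when p < 0.05 (if a p exists) or CV < 0.1
   (duplicate designs); significant sites with FC > 1.5 are **UP**, below
   1/1.5 **DOWN**. Regulated sites are binned by magnitude into Q1
   (FC ≤ 1/2), Q2 (1/2 < FC < 1/1.5), Q3 (1.5 < FC ≤ 2), Q4 (FC > 2).
4. **Functional enrichment.** Per Q-group, each GO/KEGG/domain/compartment
   term is tested with a two-sided Fisher exact test of the 2×2 table
   (k, n−k; K−k, N−n−K+k) against the background of all proteins bearing
   quantified sites; significant terms (raw p < 0.05; BH-adjusted p
   reported) form a −log10 p matrix ordered by average-linkage
   hierarchical clustering.
5. **Motif analysis.** ±10-residue windows around modified lysines
   (foreground) vs windows around *all* lysines in the proteome
   (background). Motifs are extracted motif-x style: greedily fix the
   (offset, residue) pair with the smallest binomial tail probability
   P(X ≥ k) with X ~ Binomial(n_fg, f_bg), reduce both window sets to
   matches and repeat; a position is fixed only at p < 10⁻⁶ with ≥ 20
   foreground occurrences. Patterns use the compact colon notation
   (`Kmal:C` = cysteine two residues downstream).
6. **Network & QC.** Interactions with confidence score > 0.7 among
   differential proteins, ranked by degree (top 50); per-sample log10
   intensity box-plot summaries and sample-level PCA variance fractions on
   complete-case relative values.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
experiment (2 groups × 2 replicates, 2000 sites on 300 proteins, 5%
differential sites with fold changes in [2, 4], 10% protein-confounded
sites, a planted C-at-+2 motif and a planted KEGG term):

```sh
python analysis/01_simulate.py --seed 1     # writes results/sim/
python analysis/02_quantify.py
python analysis/03_differential.py
python analysis/04_enrichment.py
python analysis/05_motifs.py
python analysis/06_network_qc.py
python analysis/07_benchmark_recovery.py
```

Output of step 03 (seed 1):

```
tested 1993 sites: UP 40, DOWN 45
Q-group counts: {'Q1': 45, 'Q4': 39, 'Q3': 1}
heatmap filter kept 85 differential sites; top-30 selected
vs truth: sensitivity 0.850, FDR 0.000
```

85 of the 100 planted sites are recovered with no false calls; the misses
are sites with a missing replicate cell, which a duplicate design cannot
screen by CV (with complete data, step 07 reports mean sensitivity 0.998
at FDR 0). Step 04 finds the planted pathway at the top of both extreme
fold-change bins:

```
KEGG: 2 significant (group, term) pairs over groups ['Q1', 'Q3', 'Q4']
  Q4 ko00620 (Pyruvate metabolism): p=6.24e-14, fold=2.77 [33/39 vs 91/298]
  Q1 ko00620 (Pyruvate metabolism): p=1.4e-11, fold=2.56 [32/41 vs 91/298]
```

and step 05 recovers the planted motif as the only one passing the
thresholds:

```
1 motif(s) at p < 1e-6, >= 20 occurrences:
  Kmal:C: fg=1167, bg=1275, fold=3.5
```

The same stages are available as shell commands (`malonmap simulate`,
`malonmap run --config pipeline.yaml`, `malonmap quantify/diff/enrich/
motif/network/qc`) and as library functions (`malonmap.pipeline.run_stages`).

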