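# Methods

This note records the statistical model behind each stage, the parameter
choices, what the synthetic data does and does not emulate, and the
numerical conventions, so that results are interpretable and reproducible.

## Relative quantification

Raw site intensities are assumed log-normal with site-specific location.
Centralization divides each site's intensities by the mean of that site's
*observed* values (missing cells, including recorded zeros, are excluded
from the mean rather than imputed — no imputation scheme is assumed).
Sites with fewer than two observed values carry no relative information
and are dropped with a logged count. On complete rows the relative values
average exactly 1, and centralization is invariant to rescaling a site's
intensities by any positive constant.

Protein correction divides the site's relative values cell-wise by the
parent protein's relative values. The correction is per-cell on purpose:
if the protein value is missing in one sample, only that cell falls back
to the uncorrected value (and is flagged), so a single protein dropout
does not discard the site. After correction, the fold change of a site
equals the group-mean ratio of per-sample site/protein intensity ratios —
protein-driven apparent regulation cancels exactly on complete data.

## Differential screen

* **Fold change** — ratio of group means of relative values, treatment
  over control, each mean over that group's observed cells.
* **CV** — replicate *m* of the treatment group is paired with replicate
  *m* of the control group in file order (the only stable pairing for an
  unlabeled duplicate design); the statistic is the sample SD (n−1) of
  the paired ratios over their mean, requiring ≥ 2 complete pairs.
* **t-test** — two-sided Welch on log2 relative values (log scale because
  the noise model is multiplicative), computed only when both groups have
  ≥ 3 observations; duplicate designs therefore fall back to the CV gate.
  Zero-variance degenerate sites give p = 1 at equal means.
* **Calls** — significant iff p < 0.05 when a p exists, else CV < 0.1;
  UP iff significant and FC > 1.5, DOWN iff FC < 1/1.5, both strict, so a
  fold change exactly at the threshold is not called.
* **Q-groups** — Q1: FC ≤ 1/2, Q2: (1/2, 1/1.5), Q3: (1.5, 2], Q4: > 2.
  The bin bounds are a package convention (config-overridable): symmetric
  quarter-bins around the regulation thresholds, chosen so that swapping
  the groups maps Q1↔Q4 and Q2↔Q3 exactly.
* **Reporting filters** — the heatmap export keeps regulated sites
  quantified in ≥ ⌈2/3 × n_samples⌉ samples; the top-N list (default 30)
  ranks by |log2 FC| descending with ties broken by smaller CV then site
  id. |log2 FC| is the package's definition of "most strongly
  differential"; no p-based ranking exists in a duplicate design.

No multiple-testing correction is applied at the site level; the screen is
a threshold rule, not an inference procedure.

## Functional enrichment

For a differential set of *n* proteins, *k* of which carry a term, against
a background of *N* proteins with *K* carriers, the two-sided Fisher exact
p sums hypergeometric probabilities of all tables with the observed
margins whose probability does not exceed the observed table's
(minimum-likelihood convention, with a 1e−7 relative tolerance on pmf
comparisons to absorb float round-off). The implementation vectorizes the
summation over the whole support, which makes exhaustive verification
against direct enumeration cheap; the test suite checks every 2×2 table
with N ≤ 60 against integer-arithmetic enumeration and cross-checks
`scipy.stats.fisher_exact` on random tables.

The default background is the proteins bearing quantified modification
sites (enrichment *within* the malonylome); callers can pass any wider
universe. Terms with no differential carrier are skipped. Benjamini–
Hochberg adjusted p-values are reported, but the significance flag uses
raw p < 0.05. The Q-group matrix holds −log10 raw p over the union of
terms significant in ≥ 1 group; hierarchical clustering uses average
linkage on Euclidean distances with untested cells treated as 0 for the
distance computation only (they stay NA in the export), and leaf order is
the deterministic scipy ordering. Linkage and distance are recorded here
as fixed conventions of the package.

## Motif discovery

Windows are 21-mers (offsets −10…+10) centered on the modified lysine,
padded with `_` past protein termini; pad characters never enter any
frequency numerator or denominator. The background is one window per
lysine in the supplied proteome, so the foreground is a subset of the
background by construction.

The extraction is the canonical greedy fix-and-reduce scheme: among all
(offset ≠ 0, residue) pairs compute the binomial tail P(X ≥ k_fg) with
X ~ Binomial(n_fg, f_bg), where f_bg is the residue frequency at that
offset among background windows matching the current partial motif
(recomputed after every reduction); fix the smallest-p pair provided
p < 10⁻⁶ and k_fg ≥ 20, reduce both sets to matching windows, and repeat.
When no pair qualifies, the motif (if it fixed ≥ 1 position) is emitted,
its foreground windows are removed from the pool, the background is
restored in full, and the search restarts, so each foreground window is
consumed by at most one motif. Ties in minimal p break by smaller
|offset| (negative before positive at equal distance) then alphabetical
residue — a deterministic convention. The binomial (not hypergeometric)
tail matches the motif-x family of tools.

The residue × offset heatmap reports log2 of foreground over background
relative frequencies with a pseudo-count of 0.5 per cell (denominator
+ 10 = 0.5 × 20 letters), keeping all entries finite and exactly 0 when
the two sets coincide.

## Network and QC

Edges at confidence ≤ 0.7 are dropped; both endpoints must be
differential proteins; connectivity is ranked by node degree (recorded
here as the package's reading of "most closely interacting").
The top 50 proteins by degree are kept (ties by degree then id); node
degrees in the exported view are recounted within the view's own edges so
the handshake identity (Σdeg = 2E) holds in every output.

QC reports per-sample five-number summaries of log10 raw intensities over
observed cells, and a sample-level PCA on the complete-case relative
value matrix (sites with any missing cell are excluded and counted —
no imputation), column-centered, with variance fractions from the
singular values truncated at n_samples − 1 components.

## Synthetic data

The generator emulates a 2-group × 2-replicate label-free PTM experiment:

| parameter | default | meaning |
|---|---|---|
| `n_proteins`, `n_sites` | 300, 2000 | proteome and site-table size |
| `seq_length_range` | 150–600 aa | i.i.d. residues; K pinned at 7% |
| `baseline_log10_mu/sigma` | 7.0, 0.5 | log-normal site intensity (~10⁷ median) |
| `frac_differential` | 0.05 | planted regulated sites |
| `true_fc_range` | [2, 4] | planted fold change (reciprocal for DOWN) |
| `replicate_noise_sigma_log2` | 0.05 | multiplicative replicate noise |
| `missing_rate` | 0.05 | completely-at-random dropout |
| `protein_confounding` | 0.10 | sites whose shift is purely protein-driven |
| `motif_spec` | C at +2, carry 0.6, bg 0.02 | planted motif |
| `enriched_terms` | carry 0.8 vs background 0.1 | planted KEGG term |

Control replicates sit at the site baseline; treatment replicates carry
the planted fold change times the replicate noise, and the protein table
is noiseless by default (`protein_noise_sigma_log2` raises it). This
makes the paired-ratio CV carry exactly one noise term per replicate and
the protein correction exact. Real data differ in ways the generator
deliberately omits: noise in both groups and in the protein table
(halving the effective CV margin), intensity-dependent dropout rather
than MCAR missingness, correlated sites on shared peptides, and
non-uniform residue composition. Passing the recovery benchmarks
therefore demonstrates correctness of the screening arithmetic and
thresholds under the stated noise model, not field performance on real
spectra.

Confounded sites are drawn from the non-regulated pool: their parent
protein receives the fold change, so the raw site intensities shift while
the modification-level truth is "no regulation" — the protein-correction
stage must rescue them to FC ≈ 1, and the benchmark measures exactly
that. Motif planting only overwrites positions that are not chosen site
centers, so the non-carrier foreground keeps the background composition
(overwriting arbitrary non-center lysines is allowed; protecting them all
would enrich K in the residual foreground and fabricate spurious motifs).

All randomness flows from the single config seed through one
`numpy.random.Generator`; a fixed config reproduces the written bundle
byte for byte.

## Problem sizes in the shipped benchmarks

The test suite and `scripts/acceptance.py` use 2000-site simulations
(10 seeds) for regulation recovery, 400-site × 10-seed noisy nulls,
3000-window backgrounds with 300–500-window foregrounds (20 null seeds,
10 planted seeds) for motif calibration, and the full N ≤ 60 table sweep
(635,375 tables) for the Fisher oracle — sizes at which every check runs
in seconds to ~1 minute while keeping estimator standard errors well
below the tolerances asserted.

## Known limitations

* The CV gate with two replicate pairs has low power against modest fold
  changes and no error-rate calibration; it is a reproducibility screen.
* The enrichment model treats annotations as flat labels (no GO-graph
  topology) and tests terms independently.
* Motif extraction is greedy; overlapping motifs compete for foreground
  windows and only the first (most significant) wins.
* Sites on the same peptide are treated as independent, as are replicate
  samples.
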