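# Methods

## The analysis chain

All primary analysis is at the gene level. Peptide reads are summed per
source gene and 0.5 pseudo-reads added, so genes with zero reads remain in
every downstream computation and all denominators are strictly positive.
Each sample column is converted to percent of its total (removing depth),
then divided gene-wise by the mean percentage across the bead-only mock-IP
controls (removing nonspecific background binding). The resulting fold
change (FC) is the unit of comparison between samples and cohorts.

z-scores standardize FC against a reference cohort, by default the
pre-exposure controls. Disease-cohort samples are scored against the full
reference; each reference sample is scored against the reference *minus
itself* (leave-one-out), so an outlier control cannot inflate the spread it
is judged against. Standard deviation uses the sample (n−1) convention,
exposed as `ddof`. Genes whose reference sd is exactly zero get NaN
("undefined"), never ±inf, and are never called positive.

Calls are thresholded inclusively: enriched iff FC ≥ 5, positive iff
z ≥ 6. The two calls are independent — enrichment never consults z and
vice versa. Thresholds are arguments and are recorded in output metadata.

Peptide-level work is deliberately restricted to reads-per-100,000
profiles: for one gene over a sample set, the mean rp100k per peptide
ordered by start position, plus a *focality* summary (share of the gene's
signal on its strongest peptide; 1.0 means one shared linear epitope,
1/k means signal spread over k peptides). An all-zero gene has undefined
(NaN) focality.

## Group statistics

Per-antigen cohort comparisons use the two-sample Kolmogorov–Smirnov test
on FC values. Direction convention: `alternative="greater"` tests whether
the first group is stochastically greater (its ECDF lies below). p-values
come from scipy (exact for small samples, asymptotic otherwise, at scipy's
`auto` crossover). The D statistic itself is recomputed in exact integer
arithmetic — max |c₁n₂ − c₂n₁| / (n₁n₂) over pooled evaluation points,
with ties handled by evaluating at the pooled points — because float ECDF
subtraction can differ from the true supremum by one ulp, which matters
when D is compared against exact oracles. One-sided D is never larger than
two-sided D, and both are invariant to strictly monotone transforms of the
data.

No multiple-testing correction is applied by default: the scan's primary
output is the raw p-value per gene, with Benjamini–Hochberg available as an
opt-in `q_value` column. Phenotype scans run one test per phenotype flag,
flagged samples versus the remaining post-infection samples, and return a
genes × phenotypes p-value matrix (the tabular form behind a heatmap).

Shared-antigen tabulation declares an antigen *present* in a cohort when at
least one sample of that cohort is enriched (FC ≥ threshold) for it.

## Classification

Cohort discrimination fits `LogisticRegression(solver="liblinear",
l1_ratio=1.0, C=1.0)` — pure L1 — on the gene × sample z-score matrix,
under stratified 5-fold cross-validation seeded for reproducibility.
Stratification avoids degenerate folds at cohort sizes of tens of samples.
Undefined z entries are imputed to 0, neutral on the standardized scale.
Each fold's model scores its held-out fifth; AUC is reported per fold and
pooled over the concatenated held-out scores, and the pooled value is the
headline number (both are emitted because either convention is common).
The reported coefficient per gene is the mean across the five fold models;
features are ranked by |coefficient| with sign retained and ties broken
lexicographically by gene id. C = 1.0 (the library default) is exposed, as
is the fold count.

## Cross-reactivity scanning

Substitution scores are the published Gonnet PAM250 matrix (loaded from
Biopython's `GONNET1992` table). Clustal column symbols follow the score
thresholds: `*` identical, `:` score > 0.5, `.` score in (0, 0.5], space
otherwise; gap columns are always blank. The physicochemical conservation
score uses the standard ten amino-acid property classes (hydrophobic,
polar, small, proline, tiny, aliphatic, aromatic, positive, negative,
charged): 11 iff identical, else the number of classes on which the pair
agrees — membership or joint absence both count. `X` (unknown residue)
scores 0 against everything and is never "identical".

Two scan modes. `ungapped_window` slides the query over every target
position and sums per-column scores (vectorized over windows).
`local` is Smith–Waterman via Biopython's `PairwiseAligner` with the same
matrix and affine gaps; a gap of length k costs open + (k−1)·extend with
Clustal-style defaults 10 and 0.2 on the Gonnet scale. Hits are ranked by
score with ties broken by (protein id, offset), so scans are deterministic.
The original mimicry analysis aligned two sequences; this is implemented as
pairwise alignment, a faithful simplification of a two-sequence "MSA".

## The synthetic cohort generator

The generator emulates the statistical structure the analysis chain
assumes, not the assay chemistry:

- **Shared background.** One background draw per library, common to all
  samples — mock-IP normalization is only meaningful if background is
  correlated across samples. Gene-level background abundance mixes a
  heavy-tailed Dirichlet component (concentration 0.3: a minority of sticky
  clones dominates bead binding, spanning orders of magnitude as real
  mock-IP counts do) with a uniform floor (default weight 0.1): every clone
  is present in the input library, so no gene's background is ever
  literally zero and a multiplicative reactivity boost always has something
  to act on. Gene abundance is split across the gene's tiled peptides by a
  moderate Dirichlet (concentration 1).
- **Per-sample variation.** Each sample multiplies the shared background by
  log-normal noise (σ = 0.25) and renormalizes; sequencing depth is
  negative-binomial around `depth_mean` (default 5×10⁵ reads, dispersion
  20); counts are multinomial given depth and proportions. No empirical
  bead-only background distribution is published for this assay; these laws
  are modeling conveniences chosen for the right qualitative behavior
  (heavy tail, overdispersion, cross-sample correlation).
- **Planted reactivity.** A planted antigen boosts the binding propensity
  of its gene's peptides (or a single focal peptide, emulating one shared
  linear epitope) multiplicatively *before* renormalization in each
  reactive sample, keeping totals realistic. Reactive samples are drawn per
  antigen at the configured prevalence from the targeted cohorts
  (optionally restricted to a phenotype flag), and every assignment is
  recorded as ground truth.
- **Determinism.** One seed governs library generation, reactive-sample
  assignment, and count draws, in that order; a fixed seed reproduces the
  cohort bit for bit.

What the generator does **not** model: phage amplification bias, PCR
duplicates, sequencing error, nucleotide-level reads, biological covariance
between antigens, or antibody affinity effects. Passing recovery tests
therefore demonstrates that the analysis chain correctly inverts the
generative structure it assumes — depth removal, background division,
reference standardization — not that it is robust to every artifact of
real immunoprecipitation data.

## Benchmark conditions (`phipkit.scenarios`)

- *Null*: 200 genes, two exchangeable post-infection arms of 60, no planted
  antigens — used to measure the two-sided scan's type-I error (raw
  p < 0.05 rate ≈ 0.05) and the cross-validated AUC at chance (≈ 0.5),
  each averaged over 10 seeds.
- *Signature*: 500 genes, ten antigens shared by both post-infection arms
  at prevalence 0.3, 60 cases vs 60 pre-exposure controls. The effect size
  (×5 on binding propensity) is calibrated so that every reactive sample
  clears the z ≥ 6 positivity bar with the z magnitudes real positives
  show (≈ 7–20). Much larger effects are counterproductive for coefficient
  ranking: z in the hundreds lets L1 separate with near-zero weights on the
  true antigens, and noise genes outrank them.
- *Prevalence*: one antigen at prevalence 0.22 across 185 post-infection
  samples (121 + 64, with 57 pre-exposure controls) and a strong effect
  (×50) — recovery of a positivity fraction from calls.
- *Focal epitope*: one antigen with the boost confined to a single
  49-residue peptide at ×10⁴ — the dominant-epitope regime in which a
  reactive sample's reads concentrate on one fragment (real dominant
  epitopes show fold changes in the thousands); expected focality > 0.9.

Problem sizes throughout (hundreds of genes, tens of samples, a few
hundred thousand reads per sample) are chosen so the full validation suite
simulates and analyzes in seconds while preserving the cohort-to-gene
ratios that make the statistics meaningful.

## Numerical and design notes

- Pseudocount is applied once, at gene level after summation, before
  percent normalization (the alternative — peptide level — changes
  results). Mock-IP percentages come from the same pseudocounted matrix, so
  the FC denominator is always positive.
- Whether positivity is "FC six standard deviations above the control
  mean" or "z ≥ 6 on FC" is the same computation; it is implemented as
  z ≥ 6.
- Fold-change and percent matrices are pure functions of their inputs;
  multiplying one sample's raw counts by a constant leaves its percent and
  FC columns unchanged up to the pseudocount's perturbation (exact in the
  no-pseudocount limit).
- `start_pos` is 0-based everywhere. Tabular delimiters are chosen by
  extension (`.csv` comma, otherwise tab); unknown residue letters are
  mapped to `X` with a warning rather than rejected.
- Pipeline runs fail fast: configuration and selector errors (including
  phenotype labels that no simulated or ingested column will satisfy)
  surface before any stage executes. Each run writes a manifest with the
  config hash and per-artifact sha256; re-running with an unchanged config
  skips stages whose outputs still match.

## Known limitations

- The classifier offers no nested cross-validation or hyperparameter
  search; C is fixed unless overridden.
- KS p-values at large, tied samples rely on scipy's asymptotic fallback.
- The cross-reactivity module reports no alignment significance (E-values);
  scores are comparative within a scan.
- Real-data ingest expects the documented tabular schemas; deposited
  datasets with other layouts need a thin adapter.
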