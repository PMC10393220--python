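# phipkit

Proteome-wide autoantibody profiling from phage immunoprecipitation
sequencing (PhIP-Seq) read counts: enrichment and positivity calling,
cohort statistics, serology classification, epitope localization, and
viral cross-reactivity scanning — with a seeded synthetic-cohort generator
for end-to-end validation.

## Who this is for

PhIP-Seq assays display tiled ~49-aa peptides on T7 phage; serum antibodies
immunoprecipitate bound phage, and sequencing read counts per peptide
quantify reactivity. `phipkit` is for analysts who have a peptide × sample
count matrix (plus bead-only mock-IP controls and a pre-exposure control
cohort) and want the standard downstream analysis: which self-proteins are
antibody targets, in what fraction of a cohort, whether reactivity patterns
separate cohorts, where within a protein the epitope sits, and whether the
epitope resembles a pathogen sequence (molecular mimicry).

## The model

For gene *g* and sample *s*, with peptide read counts collapsed per gene:

- gene reads: `G(g,s) = Σ_{p∈g} counts(p,s) + 0.5` (pseudocount keeps
  zero-read genes in the analysis),
- percent of total: `P(g,s) = 100 · G(g,s) / Σ_g G(g,s)`,
- fold change over mock IP: `FC(g,s) = P(g,s) / mean_{m∈mock} P(g,m)`,
- z-score vs a reference cohort R (default: pre-exposure controls):
  `z(g,s) = (FC(g,s) − μ_R(g)) / σ_R(g)`, where a reference sample's own
  μ, σ are recomputed **leaving that sample out**, so it never deflates its
  own score; σ_R = 0 genes are flagged undefined rather than ±∞.

Calls: *enriched* iff `FC ≥ 5`; *positive* iff `z ≥ 6` (both inclusive,
both configurable). Cohort comparisons use the two-sample
Kolmogorov–Smirnov test on FC (two-sided, or one-sided "greater in
disease"); cohort discrimination uses L1-regularized logistic regression
(liblinear) on z-scores under stratified 5-fold cross-validation, with
antigens ranked by the magnitude of their fold-averaged coefficient.
Peptide-level epitope profiles use reads per 100,000; cross-reactivity
scans score a peptide against a proteome with the Gonnet PAM250 matrix
(ungapped sliding window or Smith–Waterman), annotating each column with
Clustal symbols (`*` identical, `:` score > 0.5, `.` score in (0, 0.5])
and a 0–11 physicochemical conservation score (11 = identical, 10 = all
ten property classes conserved).

## Worked example

```python
from phipkit import (PlantedAntigen, SimulationConfig, call, collapse_to_genes,
                     fold_change, generate_library, percent_normalize,
                     positivity_fraction, simulate_cohort, zscore_vs_reference)

config = SimulationConfig(
    n_genes=100, peptides_per_gene=4,
    n_pre_controls=20, n_comparators=20, n_cases=30, n_mock_ip=8,
    depth_mean=200_000.0, seed=7,
    planted_antigens=[PlantedAntigen("GENE0042",
                                     target_cohorts=("case", "comparator"),
                                     prevalence=0.3, effect_multiplier=5.0)],
)
library = generate_library(config)
counts, sheet, truth = simulate_cohort(config, library)

fc = fold_change(percent_normalize(collapse_to_genes(counts, library)), sheet)
z = zscore_vs_reference(fc, sheet, reference_role="pre_control")
calls = call(fc, z)
print(positivity_fraction(calls, sheet, "GENE0042", {"case", "comparator"}))
print(positivity_fraction(calls, sheet, "GENE0042", {"pre_control"}))
```

prints

```
0.34
0.0
```

i.e. 34% of the 50 post-infection samples are called positive (z ≥ 6) for
the planted antigen — the simulator actually made 17 of them reactive at a
configured prevalence of 0.30 — and none of the pre-exposure controls are.
The scripts in `examples/` walk through each capability the same way:
simulation, calling, KS group scans, classification (pooled cross-validated
AUC 0.982 on a planted 10-antigen signature vs ≈ 0.5 on null cohorts),
epitope focality and proteome scanning.

## Command line

The same workflow runs end-to-end from a YAML config:

```bash
phipseq run --config config.yaml --out out/
```

with stage subcommands `simulate`, `normalize`, `call`, `compare`,
`classify`, `scan`. Every output is tabular text with a provenance comment
line; `out/manifest.json` records config hash and per-file checksums, and
re-running with an unchanged config skips stages whose outputs are intact.

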