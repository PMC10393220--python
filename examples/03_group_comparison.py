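"""Per-antigen cohort comparison with Kolmogorov–Smirnov tests.

Scans every gene's fold-change distribution between post-infection cases and
pre-exposure controls with a one-sided ("greater in disease") KS test, the
screen used to find genes with increased signal only in a disease cohort.
"""

from phipkit import (
    PlantedAntigen, SimulationConfig, antigen_scan, collapse_to_genes,
    fold_change, generate_library, percent_normalize, simulate_cohort,
)

config = SimulationConfig(
    n_genes=150, peptides_per_gene=3,
    n_pre_controls=25, n_comparators=25, n_cases=30, n_mock_ip=8,
    depth_mean=200_000.0, seed=11,
    planted_antigens=[
        PlantedAntigen("GENE0099", target_cohorts=("case",),
                       prevalence=0.5, effect_multiplier=5.0)
    ],
)
library = generate_library(config)
counts, sheet, _ = simulate_cohort(config, library)
fc = fold_change(percent_normalize(collapse_to_genes(counts, library)), sheet)

scan = antigen_scan(fc, sheet, "case", "pre_control", alternative="greater")
top = scan.sort_values("p_value").head(5)
print(top[["statistic", "p_value", "n1", "n2"]].to_string(
    float_format=lambda v: f"{v:.3g}"))
print()
print("The planted case-only antigen GENE0099 should head the list: its")
print("fold-change ECDF in cases sits below the control ECDF (stochastically")
print("greater signal), giving the largest one-sided D and smallest p.")
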