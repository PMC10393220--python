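"""Canonical synthetic study conditions used for validation.

Each builder returns a :class:`~phipkit.simulate.SimulationConfig` describing
one benchmark cohort:

* :func:`null_cohort` — no planted antigens; two exchangeable post-infection
  arms of 60 samples each.  Used for type-I-error and null-classification
  checks.
* :func:`signature_cohort` — ten antigens shared across both post-infection
  arms at 30% prevalence, with the effect sized so every reactive sample
  clears the z >= 6 positivity bar (z around 7–20, the magnitude real
  positives show), 60 cases vs 60 pre-exposure controls, 500 genes.
  The synthetic analogue of a post-infection autoreactivity signature.
* :func:`prevalence_cohort` — one shared antigen at 22% prevalence across
  185 post-infection samples (121 cases + 64 comparators, 57 pre-exposure
  controls): the recovery benchmark for positivity-fraction estimation.
* :func:`focal_epitope_cohort` — one antigen whose reactivity sits entirely
  on a single 49-residue peptide, with the very large effect a dominant
  linear epitope shows in real data (fold changes in the thousands);
  benchmark for peptide-level epitope localization.
"""

from __future__ import annotations

from .simulate import PlantedAntigen, SimulationConfig

#: gene used by the single-antigen scenarios
PREVALENCE_GENE = "GENE0010"
FOCAL_GENE = "GENE0010"


def null_cohort(seed: int, n_genes: int = 200) -> SimulationConfig:
    return SimulationConfig(
        n_genes=n_genes,
        peptides_per_gene=3,
        n_pre_controls=10,
        n_comparators=60,
        n_cases=60,
        n_mock_ip=8,
        depth_mean=300_000.0,
        seed=seed,
    )


def signature_cohort(seed: int) -> SimulationConfig:
    planted = [
        PlantedAntigen(
            gene_id=f"GENE{50 * i:04d}",
            target_cohorts=("case", "comparator"),
            prevalence=0.3,
            effect_multiplier=5.0,
        )
        for i in range(10)
    ]
    return SimulationConfig(
        n_genes=500,
        peptides_per_gene=3,
        n_pre_controls=60,
        n_comparators=30,
        n_cases=60,
        n_mock_ip=8,
        depth_mean=300_000.0,
        seed=seed,
        planted_antigens=planted,
    )


def planted_genes() -> list[str]:
    return [f"GENE{50 * i:04d}" for i in range(10)]


def prevalence_cohort(seed: int, prevalence: float = 0.22) -> SimulationConfig:
    return SimulationConfig(
        n_genes=200,
        peptides_per_gene=3,
        n_pre_controls=57,
        n_comparators=64,
        n_cases=121,
        n_mock_ip=8,
        depth_mean=300_000.0,
        seed=seed,
        planted_antigens=[
            PlantedAntigen(
                gene_id=PREVALENCE_GENE,
                target_cohorts=("case", "comparator"),
                prevalence=prevalence,
                effect_multiplier=50.0,
            )
        ],
    )


def focal_epitope_cohort(seed: int) -> SimulationConfig:
    return SimulationConfig(
        n_genes=100,
        peptides_per_gene=5,
        n_pre_controls=20,
        n_comparators=20,
        n_cases=40,
        n_mock_ip=8,
        depth_mean=300_000.0,
        seed=seed,
        planted_antigens=[
            PlantedAntigen(
                gene_id=FOCAL_GENE,
                target_cohorts=("case", "comparator"),
                prevalence=0.5,
                effect_multiplier=10_000.0,
                focal_peptide_only=True,
            )
        ],
    )
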