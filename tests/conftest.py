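import numpy as np
import pandas as pd
import pytest

from phipkit import (
    PlantedAntigen,
    SimulationConfig,
    generate_library,
    simulate_cohort,
)


@pytest.fixture
def tiny_library() -> pd.DataFrame:
    """Two genes x two peptides, hand-built."""
    return pd.DataFrame(
        {
            "gene_id": ["GA", "GA", "GB", "GB"],
            "protein_name": ["prot A"] * 2 + ["prot B"] * 2,
            "start_pos": [0, 24, 0, 24],
            "aa_seq": ["ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIK"] * 4,
        },
        index=pd.Index(["GA_p00", "GA_p01", "GB_p00", "GB_p01"], name="peptide_id"),
    )


@pytest.fixture
def tiny_sheet() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "role": ["case", "case", "pre_control", "pre_control", "pre_control",
                     "pre_control", "mock_ip", "mock_ip"],
            "phenotype_fatigue": [True, False, False, False, False, False, False, False],
        },
        index=pd.Index([f"s{i}" for i in range(8)], name="sample_id"),
    )


@pytest.fixture
def tiny_counts(tiny_library, tiny_sheet) -> pd.DataFrame:
    rng = np.random.default_rng(7)
    return pd.DataFrame(
        rng.integers(0, 100, size=(len(tiny_library), len(tiny_sheet))),
        index=tiny_library.index.copy(),
        columns=tiny_sheet.index.copy(),
    )


@pytest.fixture(scope="session")
def null_cohort():
    """Small null simulation (no planted antigens), shared across tests."""
    cfg = SimulationConfig(
        n_genes=60, peptides_per_gene=3, n_pre_controls=12, n_comparators=12,
        n_cases=12, n_mock_ip=4, depth_mean=100_000.0, seed=11,
    )
    lib = generate_library(cfg)
    counts, sheet, truth = simulate_cohort(cfg, lib)
    return cfg, lib, counts, sheet, truth


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with one fully-penetrant case antigen and one focal-epitope antigen."""
    cfg = SimulationConfig(
        n_genes=80, peptides_per_gene=4, n_pre_controls=15, n_comparators=12,
        n_cases=15, n_mock_ip=4, depth_mean=150_000.0, seed=23,
        phenotype_defs={"fatigue": 0.5},
        planted_antigens=[
            PlantedAntigen("GENE0005", ("case",), prevalence=1.0, effect_multiplier=50.0),
            PlantedAntigen("GENE0010", ("case", "comparator"), prevalence=0.5,
                           effect_multiplier=10_000.0, focal_peptide_only=True),
        ],
    )
    lib = generate_library(cfg)
    counts, sheet, truth = simulate_cohort(cfg, lib)
    return cfg, lib, counts, sheet, truth
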