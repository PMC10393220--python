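"""Seeded synthetic PhIP-Seq cohorts with ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, without modeling the wet-lab assay itself:

* a phage-display **peptide library** tiling random 49-residue fragments
  across synthetic genes;
* a **shared heavy-tailed background** of nonspecific phage binding, drawn
  once per library and common to every sample (mock-IP fold-change
  normalization is only meaningful if background is correlated across
  samples), perturbed per sample by multiplicative log-normal noise.  The
  background is two-level: gene-level abundance mixes a uniform floor (every
  clone is present in the input library) with a heavy-tailed Dirichlet
  component (concentration well below 1: a minority of sticky clones
  dominates the bead binding, as in real mock IPs), and is split across each
  gene's peptides by a moderate Dirichlet;
* **sequencing depth** varying between samples via a negative-binomial law;
* **planted antigen reactivities**: in reactive samples the binding
  propensity of a target gene's peptides (or of a single focal peptide,
  emulating a shared linear epitope) is multiplied by an effect size before
  renormalization, so totals stay realistic;
* bead-only **mock-IP samples** drawn from background alone.

One global seed governs library generation, reactive-sample assignment and
count draws, in that order, so a fixed seed reproduces the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import AA_ALPHABET, PHENOTYPE_PREFIX


@dataclass(frozen=True)
class PlantedAntigen:
    """A gene made reactive in a subset of the targeted cohorts.

    Parameters
    ----------
    gene_id:
        Target gene in the simulated library.
    target_cohorts:
        Subset of ``{"case", "comparator"}`` whose samples can be reactive.
    prevalence:
        Fraction of targeted samples that are reactive, in (0, 1].
    effect_multiplier:
        Multiplicative boost (> 1) applied to the gene's peptide binding
        propensities in reactive samples, before renormalization.
    restrict_to_phenotype:
        If set, only case samples carrying this phenotype flag are eligible.
    focal_peptide_only:
        If True, boost only the gene's first peptide — a single shared
        49-aa epitope rather than whole-protein reactivity.
    """

    gene_id: str
    target_cohorts: tuple[str, ...] = ("case",)
    prevalence: float = 0.3
    effect_multiplier: float = 50.0
    restrict_to_phenotype: str | None = None
    focal_peptide_only: bool = False

    def __post_init__(self):
        if not 0 < self.prevalence <= 1:
            raise ConfigurationError("prevalence must be in (0, 1]")
        if self.effect_multiplier <= 1:
            raise ConfigurationError("effect_multiplier must be > 1")
        bad = set(self.target_cohorts) - {"case", "comparator"}
        if bad:
            raise ConfigurationError(f"target_cohorts must be within case/comparator, got {bad}")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Defaults describe a desk-scale study: a few hundred genes tiled by a
    handful of 49-aa peptides each, cohort sizes of tens of samples, eight
    bead-only mock IPs, a mean depth of half a million reads with
    negative-binomial spread, and a heavy-tailed shared background
    (Dirichlet concentration well below 1).
    """

    n_genes: int = 200
    peptides_per_gene: int = 5
    peptide_len: int = 49
    tile_step: int = 24
    n_pre_controls: int = 30
    n_comparators: int = 30
    n_cases: int = 30
    n_mock_ip: int = 8
    depth_mean: float = 500_000.0
    depth_dispersion: float = 20.0
    background_concentration: float = 0.3
    background_floor: float = 0.1
    within_gene_concentration: float = 1.0
    sample_noise_sigma: float = 0.25
    planted_antigens: list[PlantedAntigen] = field(default_factory=list)
    phenotype_defs: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        counts = dict(
            n_genes=self.n_genes, peptides_per_gene=self.peptides_per_gene,
            peptide_len=self.peptide_len, n_pre_controls=self.n_pre_controls,
            n_comparators=self.n_comparators, n_cases=self.n_cases,
            n_mock_ip=self.n_mock_ip,
        )
        for name, v in counts.items():
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ConfigurationError(f"{name} must be an integer >= 1, got {v!r}")
        if self.depth_mean <= 0:
            raise ConfigurationError("depth_mean must be > 0")
        if self.depth_dispersion <= 0:
            raise ConfigurationError("depth_dispersion must be > 0")
        if self.background_concentration <= 0:
            raise ConfigurationError("background_concentration must be > 0")
        if self.within_gene_concentration <= 0:
            raise ConfigurationError("within_gene_concentration must be > 0")
        if not 0 <= self.background_floor < 1:
            raise ConfigurationError("background_floor must be in [0, 1)")
        for label, frac in self.phenotype_defs.items():
            if not 0 <= frac <= 1:
                raise ConfigurationError(f"phenotype '{label}' fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Which samples the simulator actually made reactive, per planted antigen."""

    records: list[tuple[str, str, bool]]  # (gene_id, sample_id, reactive)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["antigen", "sample_id", "reactive"])

    def reactive_samples(self, gene_id: str) -> list[str]:
        return [s for g, s, r in self.records if g == gene_id and r]

    def realized_prevalence(self, gene_id: str) -> float:
        rows = [(s, r) for g, s, r in self.records if g == gene_id]
        if not rows:
            raise KeyError(gene_id)
        return sum(r for _, r in rows) / len(rows)


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i:04d}" for i in range(n)]


def generate_library(config: SimulationConfig) -> pd.DataFrame:
    """Generate the peptide library: random amino-acid fragments tiling each gene.

    Consecutive peptides of a gene carry increasing ``start_pos`` (stride
    ``tile_step`` residues).  Deterministic under ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    alphabet = np.array(list(AA_ALPHABET))
    rows = []
    for gene in _gene_ids(config.n_genes):
        for k in range(config.peptides_per_gene):
            seq = "".join(rng.choice(alphabet, size=config.peptide_len))
            rows.append(
                (f"{gene}_p{k:02d}", gene, f"{gene} protein", k * config.tile_step, seq)
            )
    df = pd.DataFrame(
        rows, columns=["peptide_id", "gene_id", "protein_name", "start_pos", "aa_seq"]
    )
    return df.set_index("peptide_id")


def _draw_depths(rng: np.random.Generator, n: int, mean: float, dispersion: float) -> np.ndarray:
    # NB parameterized by mean and size (dispersion): var = mean + mean^2/size
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=n)


def simulate_cohort(
    config: SimulationConfig, library: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw a full cohort: counts (peptides x samples), sample sheet, ground truth.

    Counts per sample: depth ~ NB(depth_mean, depth_dispersion); peptide
    proportions = shared Dirichlet background x per-sample log-normal noise,
    with reactive samples' targeted peptides boosted by the planted effect
    before renormalization; counts ~ Multinomial(depth, proportions).
    Mock-IP samples are background-only.  An empty ``planted_antigens`` list
    is the null simulation, not an error.
    """
    config.validate()
    n_pep = len(library)
    if n_pep != config.n_genes * config.peptides_per_gene:
        raise ConfigurationError("library size inconsistent with config")

    sample_ids, roles = [], []
    for role, n in (
        ("pre_control", config.n_pre_controls),
        ("comparator", config.n_comparators),
        ("case", config.n_cases),
        ("mock_ip", config.n_mock_ip),
    ):
        for i in range(n):
            sample_ids.append(f"{role}_{i:03d}")
            roles.append(role)
    sheet = pd.DataFrame({"role": roles}, index=pd.Index(sample_ids, name="sample_id"))

    rng_assign = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rng_counts = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    # phenotype flags on cases
    case_ids = [s for s, r in zip(sample_ids, roles) if r == "case"]
    for label, frac in config.phenotype_defs.items():
        flags = pd.Series(False, index=sheet.index)
        flags.loc[case_ids] = rng_assign.random(len(case_ids)) < frac
        sheet[PHENOTYPE_PREFIX + label] = flags

    # reactive-sample assignment
    known = set(library["gene_id"])
    records: list[tuple[str, str, bool]] = []
    reactive_map: dict[str, list[str]] = {}
    for ag in config.planted_antigens:
        if ag.gene_id not in known:
            raise ConfigurationError(f"planted antigen {ag.gene_id} not in library")
        eligible = [
            s for s, r in zip(sample_ids, roles) if r in ag.target_cohorts
        ]
        if ag.restrict_to_phenotype is not None:
            col = PHENOTYPE_PREFIX + ag.restrict_to_phenotype
            if col not in sheet.columns:
                raise ConfigurationError(
                    f"planted antigen {ag.gene_id} restricted to undefined phenotype "
                    f"'{ag.restrict_to_phenotype}'"
                )
            eligible = [s for s in eligible if sheet.loc[s, col]]
        hits = rng_assign.random(len(eligible)) < ag.prevalence
        reactive = [s for s, h in zip(eligible, hits) if h]
        reactive_map[ag.gene_id] = reactive
        for s, h in zip(eligible, hits):
            records.append((ag.gene_id, s, bool(h)))
    truth = GroundTruth(records)

    # base construction requires gene-major library order (as generated)
    gene_blocks = library["gene_id"].to_numpy().reshape(
        config.n_genes, config.peptides_per_gene
    )
    if not (gene_blocks == gene_blocks[:, :1]).all():
        raise ConfigurationError("library must be ordered gene-major")

    # shared background propensities, one draw per library: heavy-tailed
    # gene weights split across each gene's peptides by a moderate Dirichlet
    gene_w = rng_counts.dirichlet(
        np.full(config.n_genes, config.background_concentration)
    )
    # uniform library-abundance floor keeps every clone detectable
    gene_w = (1 - config.background_floor) * gene_w + config.background_floor / config.n_genes
    splits = rng_counts.dirichlet(
        np.full(config.peptides_per_gene, config.within_gene_concentration),
        size=config.n_genes,
    )
    base = (gene_w[:, None] * splits).ravel()  # library order: gene-major
    base = np.maximum(base, 1e-12)

    gene_of = library["gene_id"].to_numpy()
    pep_index = {p: i for i, p in enumerate(library.index)}
    boost_cols: dict[str, np.ndarray] = {}
    for ag in config.planted_antigens:
        if ag.focal_peptide_only:
            gene_peps = library.index[gene_of == ag.gene_id]
            idx = np.array([pep_index[gene_peps[0]]])
        else:
            idx = np.nonzero(gene_of == ag.gene_id)[0]
        for s in reactive_map[ag.gene_id]:
            col = boost_cols.setdefault(s, np.ones(n_pep))
            col[idx] *= ag.effect_multiplier

    depths = _draw_depths(
        rng_counts, len(sample_ids), config.depth_mean, config.depth_dispersion
    )
    counts = np.empty((n_pep, len(sample_ids)), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        noise = rng_counts.lognormal(0.0, config.sample_noise_sigma, size=n_pep)
        props = base * noise
        if sid in boost_cols:
            props = props * boost_cols[sid]
        props = props / props.sum()
        counts[:, j] = rng_counts.multinomial(depths[j], props)

    count_df = pd.DataFrame(counts, index=library.index.copy(), columns=sheet.index.copy())
    return count_df, sheet, truth
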