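"""End-to-end orchestration: one config in, a directory of artifacts out.

A :class:`PipelineConfig` (usually parsed from YAML) names either on-disk
inputs (counts / library / sample sheet) or a ``simulate`` block, plus the
calling thresholds, the z-score reference cohort, a list of group contrasts,
classifier contrasts, and an optional proteome-scan block.  ``run_pipeline``
validates everything up front (fail-fast: schema and label errors surface
before any stage runs), then executes

    simulate/ingest -> gene collapse -> percent -> fold change -> z-scores
    -> calls -> KS scans per contrast -> classification per contrast
    -> optional cross-reactivity scan

writing every artifact as tabular text and recording a :class:`RunManifest`
(tool version, config hash, seeds, per-file sha256, timestamps).  Re-running
with an unchanged config skips stages whose outputs already exist with the
checksums recorded in the previous manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, classifier, crossreactivity, enrichment, group_stats, io
from .errors import ConfigurationError
from .simulate import PlantedAntigen, SimulationConfig, generate_library, simulate_cohort

log = logging.getLogger("phipkit")


@dataclasses.dataclass
class PipelineConfig:
    simulate: SimulationConfig | None = None
    counts_path: str | None = None
    library_path: str | None = None
    samplesheet_path: str | None = None
    threshold_fc: float = enrichment.DEFAULT_FC_THRESHOLD
    threshold_z: float = enrichment.DEFAULT_Z_THRESHOLD
    reference_role: str = "pre_control"
    # each contrast: dict(label, group_a, group_b, alternative)
    contrasts: list[dict] = dataclasses.field(default_factory=list)
    # each classifier contrast: dict(label, positive, negative)
    classifier_contrasts: list[dict] = dataclasses.field(default_factory=list)
    classifier_folds: int = 5
    classifier_seed: int = 0
    classifier_C: float = 1.0
    # scan block: dict(gene, proteome, mode, top_k) or None
    scan: dict | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls()
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            planted = [
                PlantedAntigen(
                    gene_id=a["gene_id"],
                    target_cohorts=tuple(a.get("target_cohorts", ("case",))),
                    prevalence=float(a.get("prevalence", 0.3)),
                    effect_multiplier=float(a.get("effect_multiplier", 50.0)),
                    restrict_to_phenotype=a.get("restrict_to_phenotype"),
                    focal_peptide_only=bool(a.get("focal_peptide_only", False)),
                )
                for a in sim.pop("planted_antigens", [])
            ]
            cfg.simulate = SimulationConfig(planted_antigens=planted, **sim)
        inputs = raw.get("inputs", {}) or {}
        cfg.counts_path = inputs.get("counts")
        cfg.library_path = inputs.get("library")
        cfg.samplesheet_path = inputs.get("samplesheet")
        thr = raw.get("thresholds", {}) or {}
        cfg.threshold_fc = float(thr.get("fc", cfg.threshold_fc))
        cfg.threshold_z = float(thr.get("z", cfg.threshold_z))
        cfg.reference_role = raw.get("reference_role", cfg.reference_role)
        cfg.contrasts = list(raw.get("contrasts", []) or [])
        cls_blk = raw.get("classifier", {}) or {}
        cfg.classifier_contrasts = list(cls_blk.get("contrasts", []) or [])
        cfg.classifier_folds = int(cls_blk.get("folds", cfg.classifier_folds))
        cfg.classifier_seed = int(cls_blk.get("seed", cfg.classifier_seed))
        cfg.classifier_C = float(cls_blk.get("C", cfg.classifier_C))
        cfg.scan = raw.get("scan")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("counts_path", "library_path", "samplesheet_path"):
                p = getattr(self, name)
                if p is None:
                    raise ConfigurationError(
                        f"config needs either a 'simulate' block or inputs.{name[:-5]}"
                    )
                if not Path(p).exists():
                    raise ConfigurationError(f"input file not found: {p}")
        else:
            self.simulate.validate()
        for c in self.contrasts:
            for key in ("label", "group_a", "group_b"):
                if key not in c:
                    raise ConfigurationError(f"contrast missing '{key}': {c}")
            if c.get("alternative", "two_sided") not in ("two_sided", "greater"):
                raise ConfigurationError(f"bad alternative in contrast {c['label']}")
        for c in self.classifier_contrasts:
            for key in ("label", "positive", "negative"):
                if key not in c:
                    raise ConfigurationError(f"classifier contrast missing '{key}': {c}")
        if self.scan is not None and "gene" not in self.scan:
            raise ConfigurationError("scan block requires 'gene'")
        if self.simulate is not None:
            # fail-fast: every string selector must resolve to a role or a
            # phenotype column the simulator will actually generate
            known = set(io.ROLES) | {
                io.PHENOTYPE_PREFIX + label for label in self.simulate.phenotype_defs
            }
            for c in self.contrasts:
                for key in ("group_a", "group_b"):
                    sel = c[key]
                    if isinstance(sel, str) and sel not in known:
                        raise ConfigurationError(
                            f"contrast '{c['label']}': selector '{sel}' does not "
                            f"match any simulated role or phenotype column"
                        )
            for c in self.classifier_contrasts:
                for key in ("positive", "negative"):
                    sel = c[key]
                    if isinstance(sel, str) and sel not in known:
                        raise ConfigurationError(
                            f"classifier contrast '{c['label']}': unknown selector '{sel}'"
                        )

    def config_hash(self) -> str:
        blob = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclasses.dataclass
class RunManifest:
    version: str
    config_hash: str
    seeds: dict
    checksums: dict  # relative path -> sha256
    stages: list[str]
    started: float
    finished: float | None = None
    failed_stage: str | None = None

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _validate_phenotype_labels(config: PipelineConfig, sheet: pd.DataFrame) -> None:
    known = set(sheet["role"]) | set(sheet.columns)
    for c in config.contrasts:
        for key in ("group_a", "group_b"):
            sel = c[key]
            if isinstance(sel, str) and sel not in known:
                raise ConfigurationError(
                    f"contrast '{c['label']}': selector '{sel}' is neither a role "
                    f"nor a sample-sheet column"
                )
    for c in config.classifier_contrasts:
        for key in ("positive", "negative"):
            sel = c[key]
            if isinstance(sel, str) and sel not in known:
                raise ConfigurationError(
                    f"classifier contrast '{c['label']}': unknown selector '{sel}'"
                )


def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Execute the full workflow; see module docstring for the stage order."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()

    prev: RunManifest | None = None
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        try:
            candidate = RunManifest.load(manifest_path)
            if candidate.config_hash == cfg_hash and candidate.failed_stage is None:
                prev = candidate
        except Exception:  # corrupt manifest: recompute everything
            prev = None

    manifest = RunManifest(
        version=__version__,
        config_hash=cfg_hash,
        seeds={"simulate": config.simulate.seed if config.simulate else None,
               "classifier": config.classifier_seed},
        checksums={},
        stages=[],
        started=time.time(),
    )

    def fresh(*names: str) -> bool:
        """True if all named outputs exist with the previous run's checksums."""
        if prev is None:
            return False
        for n in names:
            p = out / n
            if n not in prev.checksums or not p.exists():
                return False
            if _sha256(p) != prev.checksums[n]:
                return False
        return True

    def record(stage: str, *names: str) -> None:
        manifest.stages.append(stage)
        for n in names:
            manifest.checksums[n] = _sha256(out / n)

    current = "ingest"
    try:
        # ---- stage: simulate / ingest ------------------------------------
        sim_files = ("counts.tsv", "library.tsv", "samplesheet.tsv", "ground_truth.tsv")
        if config.simulate is not None:
            if fresh(*sim_files):
                log.info("simulate: outputs fresh, skipping")
                counts = io.read_counts(out / "counts.tsv")
                library = io.read_library(out / "library.tsv")
                sheet = io.read_samplesheet(out / "samplesheet.tsv")
            else:
                library = generate_library(config.simulate)
                counts, sheet, truth = simulate_cohort(config.simulate, library)
                io.write_counts(counts, out / "counts.tsv")
                io.write_library(library, out / "library.tsv")
                io.write_samplesheet(sheet, out / "samplesheet.tsv")
                io.write_ground_truth(truth, out / "ground_truth.tsv")
            record("simulate", *sim_files)
        else:
            counts = io.read_counts(config.counts_path)
            library = io.read_library(config.library_path)
            sheet = io.read_samplesheet(config.samplesheet_path)
            manifest.stages.append("ingest")
        io.validate_consistency(counts, library, sheet)
        _validate_phenotype_labels(config, sheet)

        # ---- stage: normalize --------------------------------------------
        current = "normalize"
        genes = enrichment.collapse_to_genes(counts, library)
        percent = enrichment.percent_normalize(genes)
        fc = enrichment.fold_change(percent, sheet)
        z = enrichment.zscore_vs_reference(fc, sheet, config.reference_role)
        io.write_matrix(genes, out / "gene_counts.tsv", "gene reads + 0.5 pseudocount")
        io.write_matrix(percent, out / "percent.tsv", "percent of total reads per sample")
        io.write_matrix(fc, out / "fold_change.tsv", "fold change over mock IP")
        io.write_matrix(z, out / "zscores.tsv",
                        f"z vs {config.reference_role} (leave-one-out within reference)")
        record("normalize", "gene_counts.tsv", "percent.tsv", "fold_change.tsv", "zscores.tsv")

        # ---- stage: call ---------------------------------------------------
        current = "call"
        calls = enrichment.call(fc, z, config.threshold_fc, config.threshold_z)
        calls_df = calls.to_frame()
        with open(out / "calls.tsv", "w") as fh:
            fh.write(f"# phipkit {__version__} | calls "
                     f"(fc>={config.threshold_fc}, z>={config.threshold_z})\n")
            calls_df.to_csv(fh, sep="\t", index=False)
        record("call", "calls.tsv")

        # ---- stage: compare ------------------------------------------------
        current = "compare"
        for c in config.contrasts:
            scan = group_stats.antigen_scan(
                fc, sheet, c["group_a"], c["group_b"],
                alternative=c.get("alternative", "two_sided"),
            )
            name = f"ks_{c['label']}.tsv"
            io.write_matrix(scan, out / name, f"KS scan {c['label']}")
            record(f"compare:{c['label']}", name)

        # ---- stage: classify -----------------------------------------------
        current = "classify"
        if config.classifier_contrasts:
            defs = {
                c["label"]: (c["positive"], c["negative"])
                for c in config.classifier_contrasts
            }
            results = classifier.subgroup_classifications(
                z, sheet, defs,
                folds=config.classifier_folds,
                seed=config.classifier_seed,
                C=config.classifier_C,
            )
            summary_rows = []
            for label, res in results.items():
                if res is None:
                    summary_rows.append((label, 0, 0, float("nan"), float("nan")))
                    continue
                coef_name = f"coefficients_{label}.tsv"
                io.write_matrix(
                    res.coefficients.to_frame(), out / coef_name,
                    f"L1 logistic coefficients, contrast {label}",
                )
                roc_name = f"roc_{label}.tsv"
                with open(out / roc_name, "w") as fh:
                    fh.write(f"# phipkit {__version__} | pooled ROC, contrast {label}\n")
                    res.roc.to_csv(fh, sep="\t", index=False)
                summary_rows.append(
                    (label, res.n_pos, res.n_neg, res.pooled_auc, res.mean_fold_auc)
                )
                record(f"classify:{label}", coef_name, roc_name)
            summary = pd.DataFrame(
                summary_rows,
                columns=["contrast", "n_pos", "n_neg", "pooled_auc", "mean_fold_auc"],
            )
            with open(out / "classification_summary.tsv", "w") as fh:
                fh.write(f"# phipkit {__version__} | classification summary "
                         f"(seed={config.classifier_seed})\n")
                summary.to_csv(fh, sep="\t", index=False)
            record("classify", "classification_summary.tsv")

        # ---- stage: scan ---------------------------------------------------
        current = "scan"
        if config.scan is not None:
            blk = config.scan
            proteome = io.read_proteome(blk["proteome"])
            gene = blk["gene"]
            non_mock = sheet.index[sheet["role"] != "mock_ip"]
            profile = enrichment.peptide_profile(counts, library, gene, non_mock)
            focal = profile.per_peptide["mean_rp100k"].idxmax()
            query = library.loc[focal, "aa_seq"]
            hits = crossreactivity.scan_proteome(
                query, proteome,
                mode=blk.get("mode", "ungapped_window"),
                top_k=int(blk.get("top_k", 5)),
            )
            hit_df = crossreactivity.hits_to_frame(hits)
            with open(out / "scan_hits.tsv", "w") as fh:
                fh.write(f"# phipkit {__version__} | cross-reactivity scan: "
                         f"gene {gene}, focal peptide {focal}\n")
                hit_df.to_csv(fh, sep="\t", index=False)
            record("scan", "scan_hits.tsv")
    except Exception:
        manifest.failed_stage = current
        manifest.finished = time.time()
        manifest.save(manifest_path)
        raise

    manifest.finished = time.time()
    manifest.save(manifest_path)
    return manifest
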