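"""Normalization and antibody-reactivity calling.

The chain, applied to a raw peptide x sample count matrix:

1. **Gene collapse** — reads of all peptides mapping to one gene are summed
   and 0.5 pseudo-reads added, so genes with zero reads stay in the analysis.
2. **Percent normalization** — each sample column is converted to percentage
   of its total, removing sequencing-depth differences.
3. **Fold change (FC) over mock IP** — each gene's percentage is divided by
   the mean percentage of that gene across the bead-only mock-IP controls,
   removing nonspecific background binding.
4. **z-scores** — FC values standardized against a reference control cohort
   (by default the pre-exposure controls).  Reference samples themselves are
   scored leave-one-out: each against the remaining controls, so a sample
   never inflates its own reference distribution.
5. **Calls** — a sample is *enriched* for a gene at FC >= 5 and *positive*
   at z >= 6 (both thresholds inclusive and configurable).

Peptide-level work stays on reads-per-100,000 profiles
(:func:`peptide_profile`), used to localize epitopes within a protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConsistencyError, LookupError_, PreconditionError

DEFAULT_FC_THRESHOLD = 5.0
DEFAULT_Z_THRESHOLD = 6.0


def collapse_to_genes(counts: pd.DataFrame, library: pd.DataFrame) -> pd.DataFrame:
    """Sum peptide reads per gene and add the 0.5 pseudocount.

    Every gene in the library appears in the output, including genes whose
    peptides all have zero reads (value 0.5).
    """
    orphans = counts.index.difference(library.index)
    if len(orphans):
        raise ConsistencyError(
            f"peptide(s) in counts absent from library: {list(orphans[:5])}"
        )
    genes = counts.groupby(library.loc[counts.index, "gene_id"]).sum()
    all_genes = pd.Index(sorted(library["gene_id"].unique()), name="gene_id")
    genes = genes.reindex(all_genes, fill_value=0).astype(float) + 0.5
    return genes


def percent_normalize(genes: pd.DataFrame) -> pd.DataFrame:
    """Convert each sample column to percentage of its total (sums to 100)."""
    return 100.0 * genes / genes.sum(axis=0)


def mock_ip_samples(samplesheet: pd.DataFrame) -> pd.Index:
    return samplesheet.index[samplesheet["role"] == "mock_ip"]


def fold_change(percent: pd.DataFrame, samplesheet: pd.DataFrame) -> pd.DataFrame:
    """Fold change over mock IP: percentage / mean mock-IP percentage per gene.

    Mock-IP columns are kept in the output for diagnostics (their FC
    fluctuates around 1).  Requires at least one mock-IP sample.
    """
    mocks = mock_ip_samples(samplesheet).intersection(percent.columns)
    if len(mocks) == 0:
        raise PreconditionError("fold_change requires >= 1 mock_ip sample")
    denom = percent[mocks].mean(axis=1)
    return percent.div(denom, axis=0)


def zscore_vs_reference(
    fc: pd.DataFrame,
    samplesheet: pd.DataFrame,
    reference_role: str = "pre_control",
    ddof: int = 1,
) -> pd.DataFrame:
    """Standardize FC against a reference cohort; leave-one-out for its members.

    For a sample outside the reference cohort, ``z = (FC - mean_ref) / sd_ref``
    with mean/sd over the full reference.  For a reference sample, mean and sd
    are recomputed over the reference *excluding that sample*, so its own
    signal cannot dampen its score.  Genes whose reference sd is zero get NaN
    (undefined), never +/-inf.

    ``ddof=1`` (sample sd) by default.
    """
    ref = samplesheet.index[samplesheet["role"] == reference_role]
    ref = ref.intersection(fc.columns)
    if len(ref) < 3:
        raise PreconditionError(
            f"reference cohort '{reference_role}' has {len(ref)} samples; need >= 3"
        )
    vals = fc[ref].to_numpy(dtype=float)
    mean_all = vals.mean(axis=1)
    sd_all = vals.std(axis=1, ddof=ddof)

    z = pd.DataFrame(np.nan, index=fc.index, columns=fc.columns)
    others = fc.columns.difference(ref)
    with np.errstate(invalid="ignore", divide="ignore"):
        z_others = (fc[others].to_numpy() - mean_all[:, None]) / sd_all[:, None]
    z_others[:, :] = np.where(sd_all[:, None] > 0, z_others, np.nan)
    z[others] = z_others

    for j, r in enumerate(ref):
        rest = np.delete(vals, j, axis=1)
        m = rest.mean(axis=1)
        s = rest.std(axis=1, ddof=ddof)
        with np.errstate(invalid="ignore", divide="ignore"):
            zr = (vals[:, j] - m) / s
        z[r] = np.where(s > 0, zr, np.nan)
    return z[fc.columns]


@dataclass
class CallTable:
    """Boolean enrichment/positivity calls per (gene, sample).

    ``enriched`` and ``positive`` are gene x sample boolean frames;
    ``z_defined`` marks where the z-score existed (reference sd > 0).
    Thresholds used are recorded on the object.
    """

    enriched: pd.DataFrame
    positive: pd.DataFrame
    z_defined: pd.DataFrame
    threshold_fc: float
    threshold_z: float

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: gene_id, sample_id, enriched, positive, z_defined."""
        out = pd.DataFrame(
            {
                "enriched": self.enriched.stack(),
                "positive": self.positive.stack(),
                "z_defined": self.z_defined.stack(),
            }
        )
        out.index.names = ["gene_id", "sample_id"]
        return out.reset_index()


def call(
    fc: pd.DataFrame,
    z: pd.DataFrame,
    threshold_fc: float = DEFAULT_FC_THRESHOLD,
    threshold_z: float = DEFAULT_Z_THRESHOLD,
) -> CallTable:
    """Threshold FC and z into enriched/positive calls (boundaries inclusive).

    The two calls are independent: enrichment looks only at FC, positivity
    only at z.  Undefined z (NaN) is never positive.
    """
    if not (fc.index.equals(z.index) and fc.columns.equals(z.columns)):
        raise PreconditionError("fold-change and z matrices are not aligned")
    z_defined = z.notna()
    return CallTable(
        enriched=fc >= threshold_fc,
        positive=z.ge(threshold_z) & z_defined,
        z_defined=z_defined,
        threshold_fc=threshold_fc,
        threshold_z=threshold_z,
    )


@dataclass
class PeptideProfile:
    """Reads-per-100,000 profile of one gene's peptides over a sample set.

    ``per_peptide`` is ordered by ``start_pos`` with columns ``start_pos``
    and ``mean_rp100k``; ``focality`` is the fraction of the gene's total
    signal carried by its single strongest peptide (1.0 = one shared linear
    epitope, 1/k = signal spread evenly over k peptides).
    """

    gene_id: str
    per_peptide: pd.DataFrame
    focality: float


def peptide_profile(
    counts: pd.DataFrame,
    library: pd.DataFrame,
    gene: str,
    samples: Iterable[str],
) -> PeptideProfile:
    """Mean reads-per-100,000 per peptide of ``gene`` over ``samples``.

    Totals are each sample's raw read total over the whole library, so the
    profile is comparable across samples of different depth.
    """
    samples = list(samples)
    if not samples:
        raise PreconditionError("peptide_profile requires a nonempty sample set")
    mask = library["gene_id"] == gene
    if not mask.any():
        raise LookupError_(f"unknown gene '{gene}'")
    peps = library.index[mask]
    missing = peps.difference(counts.index)
    if len(missing):
        raise ConsistencyError(f"library peptides missing from counts: {list(missing[:5])}")
    totals = counts[samples].sum(axis=0).astype(float)
    rp100k = 1e5 * counts.loc[peps, samples] / totals
    mean_rp = rp100k.mean(axis=1)
    out = pd.DataFrame(
        {"start_pos": library.loc[peps, "start_pos"], "mean_rp100k": mean_rp}
    ).sort_values("start_pos")
    total = out["mean_rp100k"].sum()
    focality = float(out["mean_rp100k"].max() / total) if total > 0 else float("nan")
    return PeptideProfile(gene_id=gene, per_peptide=out, focality=focality)


def positivity_fraction(
    calls: CallTable,
    samplesheet: pd.DataFrame,
    gene: str,
    cohort: Iterable[str],
) -> float:
    """Share of samples in the given role set called positive for ``gene``."""
    roles = set(cohort)
    members = samplesheet.index[samplesheet["role"].isin(roles)]
    members = members.intersection(calls.positive.columns)
    if len(members) == 0:
        raise PreconditionError(f"no samples with role in {sorted(roles)}")
    if gene not in calls.positive.index:
        raise LookupError_(f"unknown gene '{gene}'")
    return float(calls.positive.loc[gene, members].mean())
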