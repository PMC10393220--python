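"""Per-antigen cohort comparisons.

Group differences in fold-change signal are assessed with the two-sample
Kolmogorov–Smirnov test — two-sided for general comparisons, one-sided
("greater") when specifically hunting genes with signal increased only in a
disease cohort.  :func:`antigen_scan` runs the test gene-by-gene between two
sample selections, e.g. each long-COVID symptom phenotype against the
remaining post-infection samples; :func:`shared_antigens` tabulates which of
a ranked antigen list are present (>= 1 enriched sample) in each cohort.

p-values come straight from scipy's implementation (exact for small samples,
asymptotic otherwise, per its ``mode="auto"`` crossover); no multiple-testing
correction is applied by default, with Benjamini–Hochberg available as an
opt-in column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PreconditionError

_ALTERNATIVES = ("two_sided", "greater")
# Direction convention: alternative="greater" tests whether x is
# stochastically GREATER than y (its ECDF lies below y's); maps to scipy's
# alternative="less", which is phrased in terms of the CDF of x.
_SCIPY_ALT = {"two_sided": "two-sided", "greater": "less"}


@dataclass(frozen=True)
class KSResult:
    gene_id: str
    statistic: float
    p_value: float
    alternative: str
    n1: int
    n2: int


def ks_two_sample(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two_sided",
    gene_id: str = "",
    mode: str = "auto",
) -> KSResult:
    """Two-sample KS test.

    ``alternative="two_sided"``: D = sup_t |F_x(t) - F_y(t)|.
    ``alternative="greater"``: D = sup_t (F_y(t) - F_x(t)), i.e. evidence
    that x is stochastically greater than y.

    ``mode`` forwards to scipy ("auto" = exact p for small samples,
    asymptotic otherwise).
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise PreconditionError("ks_two_sample requires n1, n2 >= 2")
    res = stats.ks_2samp(x, y, alternative=_SCIPY_ALT[alternative], method=mode)
    # recompute D in integer arithmetic at the pooled evaluation points so the
    # statistic is the correctly rounded rational c1*n2 - c2*n1 over n1*n2,
    # immune to float cancellation in the ECDF subtraction
    pooled = np.concatenate([x, y])
    c1 = np.searchsorted(np.sort(x), pooled, side="right")
    c2 = np.searchsorted(np.sort(y), pooled, side="right")
    diffs = c1 * n2 - c2 * n1
    if alternative == "two_sided":
        d = int(np.abs(diffs).max()) / (n1 * n2)
    else:
        d = max(int((-diffs).max()), 0) / (n1 * n2)
    return KSResult(
        gene_id=gene_id,
        statistic=d,
        p_value=float(res.pvalue),
        alternative=alternative,
        n1=n1,
        n2=n2,
    )


def _resolve_selector(samplesheet: pd.DataFrame, selector) -> pd.Index:
    """A selector is a role name, a boolean (phenotype) column, a
    ``column=value`` covariate test (e.g. ``sex=F``), a boolean mask, or an
    explicit iterable of sample ids."""
    if isinstance(selector, str):
        if selector in set(samplesheet["role"]):
            return samplesheet.index[samplesheet["role"] == selector]
        if selector in samplesheet.columns:
            return samplesheet.index[samplesheet[selector].astype(bool)]
        if "=" in selector:
            col, _, val = selector.partition("=")
            if col not in samplesheet.columns:
                raise PreconditionError(f"selector column '{col}' not in sample sheet")
            return samplesheet.index[samplesheet[col].astype(str) == val]
        raise PreconditionError(f"selector '{selector}' is neither a role nor a column")
    if isinstance(selector, pd.Series):
        return samplesheet.index[selector.reindex(samplesheet.index, fill_value=False)]
    return pd.Index(list(selector))


def antigen_scan(
    fc: pd.DataFrame,
    samplesheet: pd.DataFrame,
    group_a,
    group_b,
    alternative: str = "two_sided",
    adjust: bool = False,
) -> pd.DataFrame:
    """KS test per gene between two disjoint sample selections on FC values.

    Returns a DataFrame (gene_id, statistic, p_value, n1, n2, alternative),
    sortable by p.  With ``adjust=True`` a Benjamini–Hochberg ``q_value``
    column is appended (off by default; raw p-values are the primary output).
    """
    a = _resolve_selector(samplesheet, group_a).intersection(fc.columns)
    b = _resolve_selector(samplesheet, group_b).intersection(fc.columns)
    if len(a) == 0 or len(b) == 0:
        raise PreconditionError("both sample selections must be nonempty")
    if len(a.intersection(b)):
        raise PreconditionError("sample selections overlap")
    xa = fc[a].to_numpy(dtype=float)
    xb = fc[b].to_numpy(dtype=float)
    rows = []
    for i, gene in enumerate(fc.index):
        r = ks_two_sample(xa[i], xb[i], alternative=alternative, gene_id=gene)
        rows.append((gene, r.statistic, r.p_value, r.n1, r.n2, alternative))
    out = pd.DataFrame(
        rows, columns=["gene_id", "statistic", "p_value", "n1", "n2", "alternative"]
    ).set_index("gene_id")
    if adjust:
        out["q_value"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def phenotype_scan(
    fc: pd.DataFrame,
    samplesheet: pd.DataFrame,
    phenotype_columns: Iterable[str],
    within_roles: tuple[str, ...] = ("case", "comparator"),
    alternative: str = "greater",
) -> pd.DataFrame:
    """One scan per phenotype: flagged samples vs the remaining samples
    within ``within_roles``.  Returns a genes x phenotypes p-value matrix
    (the tabular input behind a phenotype heatmap)."""
    pool = samplesheet.index[samplesheet["role"].isin(within_roles)]
    cols = {}
    for col in phenotype_columns:
        flagged = pool.intersection(
            samplesheet.index[samplesheet[col].astype(bool)]
        )
        rest = pool.difference(flagged)
        scan = antigen_scan(fc, samplesheet, flagged, rest, alternative=alternative)
        cols[col] = scan["p_value"]
    return pd.DataFrame(cols, index=fc.index)


def shared_antigens(
    calls,
    samplesheet: pd.DataFrame,
    ranked_genes: Sequence[str],
    rank_source: str = "coefficient",
) -> pd.DataFrame:
    """Presence of each top-ranked antigen across the three cohorts.

    An antigen is *present* in a cohort when at least one of its samples is
    enriched (FC >= threshold).  Lists longer than the gene set are truncated
    without error.  The returned frame carries summary counts in ``attrs``.
    """
    if len(ranked_genes) < 1:
        raise PreconditionError("ranked_genes must contain at least one gene")
    genes = [g for g in ranked_genes if g in calls.enriched.index]
    cohorts = {
        "present_in_case": samplesheet.index[samplesheet["role"] == "case"],
        "present_in_comparator": samplesheet.index[samplesheet["role"] == "comparator"],
        "present_in_pre": samplesheet.index[samplesheet["role"] == "pre_control"],
    }
    rows = {}
    for name, members in cohorts.items():
        members = members.intersection(calls.enriched.columns)
        rows[name] = calls.enriched.loc[genes, members].any(axis=1)
    out = pd.DataFrame(rows, index=pd.Index(genes, name="gene_id"))
    out["rank_source"] = rank_source
    out.attrs["n_present_in_both_post"] = int(
        (out["present_in_case"] & out["present_in_comparator"]).sum()
    )
    out.attrs["n_present_in_pre"] = int(out["present_in_pre"].sum())
    return out
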