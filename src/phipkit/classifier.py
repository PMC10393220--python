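"""Cohort discrimination from z-scored reactivity profiles.

An L1-regularized logistic regression (liblinear solver) is trained on the
gene x sample z-score matrix to separate two sample groups — e.g. prior
infection vs pre-exposure controls — under stratified 5-fold
cross-validation: each fold is scored by a model fit on the other four.
The sparse L1 penalty doubles as feature selection; genes are ranked by the
magnitude of their coefficient (averaged across the five fold models), and
the top-ranked antigens are the candidate signature.

AUC is reported per fold and pooled over the concatenated held-out decision
scores; the pooled value is the headline number.  Undefined z entries
(reference sd = 0) are imputed to 0, neutral on the standardized scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .errors import PreconditionError


@dataclass
class ClassifierResult:
    """Cross-validated classifier output for one contrast."""

    coefficients: pd.Series          # per gene, mean over fold models
    fold_aucs: list[float]
    pooled_auc: float
    mean_fold_auc: float
    roc: pd.DataFrame                # fpr, tpr, threshold on pooled scores
    fold_assignments: pd.Series      # fold index per sample
    pooled_scores: pd.Series         # held-out decision score per sample
    labels: pd.Series
    C: float
    seed: int
    n_pos: int = 0
    n_neg: int = 0
    warnings: list[str] = field(default_factory=list)


def fit_and_evaluate(
    z: pd.DataFrame,
    labels: Sequence[int] | pd.Series,
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> ClassifierResult:
    """Stratified k-fold CV of an L1 liblinear logistic regression on z-scores.

    ``z`` is genes x samples; ``labels`` is binary per sample (index-aligned
    if a Series).  Deterministic under ``seed`` (fold shuffling and solver
    tie-breaking).  Raises :class:`PreconditionError` if a class is absent or
    smaller than the fold count.
    """
    if isinstance(labels, pd.Series):
        labels = labels.reindex(z.columns)
        if labels.isna().any():
            raise PreconditionError("labels missing for some samples")
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise PreconditionError("labels must contain both classes (0 and 1)")
    if folds < 2:
        raise PreconditionError("folds must be >= 2")
    minority = min((y == 0).sum(), (y == 1).sum())
    if folds > minority:
        raise PreconditionError(
            f"{folds} folds but minority class has only {minority} samples"
        )

    X = z.T.to_numpy(dtype=float)  # samples x genes
    X = np.nan_to_num(X, nan=0.0)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    coefs = np.zeros((folds, X.shape[1]))
    fold_aucs: list[float] = []
    scores = np.empty(len(y))
    assign = np.empty(len(y), dtype=int)
    for k, (train, test) in enumerate(skf.split(X, y)):
        # l1_ratio=1.0 is the pure L1 (lasso) penalty under liblinear
        model = LogisticRegression(
            solver="liblinear", l1_ratio=1.0, C=C, random_state=seed
        )
        model.fit(X[train], y[train])
        s = model.decision_function(X[test])
        scores[test] = s
        assign[test] = k
        coefs[k] = model.coef_[0]
        if len(np.unique(y[test])) == 2:
            fold_aucs.append(float(roc_auc_score(y[test], s)))
        else:
            fold_aucs.append(float("nan"))

    pooled_auc = float(roc_auc_score(y, scores))
    fpr, tpr, thr = roc_curve(y, scores)
    return ClassifierResult(
        coefficients=pd.Series(coefs.mean(axis=0), index=z.index, name="coefficient"),
        fold_aucs=fold_aucs,
        pooled_auc=pooled_auc,
        mean_fold_auc=float(np.nanmean(fold_aucs)),
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        fold_assignments=pd.Series(assign, index=z.columns, name="fold"),
        pooled_scores=pd.Series(scores, index=z.columns, name="score"),
        labels=pd.Series(y, index=z.columns, name="label"),
        C=C,
        seed=seed,
        n_pos=int(y.sum()),
        n_neg=int((1 - y).sum()),
    )


def top_features(result: ClassifierResult, k: int = 20) -> pd.DataFrame:
    """Top-k genes by |coefficient| (sign retained; ties broken by gene_id)."""
    if k <= 0:
        raise ValueError("k must be positive")
    df = result.coefficients.rename_axis("gene_id").reset_index()
    df["abs_coef"] = df["coefficient"].abs()
    df = df.sort_values(
        ["abs_coef", "gene_id"], ascending=[False, True], kind="mergesort"
    ).head(k)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.drop(columns="abs_coef").set_index("gene_id")


def subgroup_classifications(
    z: pd.DataFrame,
    samplesheet: pd.DataFrame,
    subgroup_defs: Mapping[str, tuple],
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> dict[str, ClassifierResult | None]:
    """One classifier per subgroup contrast.

    ``subgroup_defs`` maps a label to ``(positive_selector, negative_selector)``
    — each a role name, a sample-sheet column, or an explicit id list (see
    :func:`phipkit.group_stats.antigen_scan` selectors).  Contrasts too small
    to cross-validate are skipped: their entry is ``None`` and a warning is
    emitted.
    """
    import warnings as _warnings

    from .group_stats import _resolve_selector

    out: dict[str, ClassifierResult | None] = {}
    for label, (pos_sel, neg_sel) in subgroup_defs.items():
        pos = _resolve_selector(samplesheet, pos_sel).intersection(z.columns)
        neg = _resolve_selector(samplesheet, neg_sel).intersection(z.columns)
        neg = neg.difference(pos)
        if min(len(pos), len(neg)) < folds:
            _warnings.warn(
                f"subgroup '{label}' too small to cross-validate "
                f"({len(pos)} vs {len(neg)}); skipped"
            )
            out[label] = None
            continue
        cols = pos.append(neg)
        labels = pd.Series(
            np.r_[np.ones(len(pos), int), np.zeros(len(neg), int)], index=cols
        )
        out[label] = fit_and_evaluate(z[cols], labels, folds=folds, seed=seed, C=C)
    return out
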