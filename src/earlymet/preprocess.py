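"""Feature reliability filtering and PCA-based batch-effect removal.

Three steps precede any modelling of a normalized log-scale expression
matrix:

1. drop features measured by fewer than four probes or flagged as
   cross-hybridizing (annotation-based filter);
2. drop the features with the highest technical variance, estimated across
   replicate profiles of a cell-line control run with every batch (top 10%
   by default);
3. remove the principal components of the sample space most associated with
   processing batch: the first ``n_examine`` components are scored by the
   R-squared of a one-way ANOVA of component scores on batch label, and the
   ``n_remove`` highest-R2 components are subtracted from the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BatchCorrectionResult",
    "filter_features_by_metadata",
    "filter_features_by_technical_variance",
    "remove_batch_components",
]


@dataclass
class BatchCorrectionResult:
    """Outcome of batch-component removal.

    Attributes
    ----------
    corrected : DataFrame
        Expression matrix with the selected components subtracted; same
        shape, index and columns as the input.
    removed_component_indices : list of int
        1-based indices (by variance rank) of the removed components.
    batch_r2_per_pc : ndarray
        One-way-ANOVA R2 of component scores on batch, for each examined PC.
    variance_captured : float
        Fraction of total (feature-centred) variance carried by the examined
        components.
    """

    corrected: pd.DataFrame
    removed_component_indices: list[int]
    batch_r2_per_pc: np.ndarray
    variance_captured: float
    removed_directions: np.ndarray = field(repr=False, default=None)  # sample space
    removed_loadings: np.ndarray = field(repr=False, default=None)  # feature space
    feature_means: np.ndarray = field(repr=False, default=None)

    def apply(self, expr: pd.DataFrame) -> pd.DataFrame:
        """Project new samples off the removed (feature-space) directions.

        Used when the correction was fitted on the training split only and
        must be applied to withheld samples.
        """
        X = expr.to_numpy(dtype=float)
        Xc = X - self.feature_means
        for u in self.removed_loadings.T:
            Xc -= np.outer(u, u @ Xc)
        return pd.DataFrame(Xc + self.feature_means, index=expr.index, columns=expr.columns)


def filter_features_by_metadata(expr: pd.DataFrame, feats: pd.DataFrame) -> pd.DataFrame:
    """Retain features with probe_count >= 4 and crosshyb == False.

    Order is preserved. Raises ``KeyError`` naming the offender if a feature
    in the matrix has no annotation row.
    """
    missing = expr.index.difference(feats.index)
    if len(missing) > 0:
        raise KeyError(f"features missing from annotation: {list(missing[:5])}")
    ann = feats.loc[expr.index]
    keep = (ann["probe_count"] >= 4) & (~ann["crosshyb"].astype(bool))
    return expr.loc[keep.to_numpy()]


def filter_features_by_technical_variance(
    expr: pd.DataFrame, tech: pd.DataFrame, top_frac: float = 0.10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop features in the top ``top_frac`` of technical variance.

    Variance is the per-feature sample variance (ddof=1) across the columns
    of ``tech``. The cutoff is the ``1 - top_frac`` quantile of the variances
    over *all* features in ``tech`` (the replicate experiment), and every
    feature of ``expr`` with variance at or above it is removed — ties at the
    cutoff all go. ``tech`` may cover a superset of the features in ``expr``;
    because the cutoff is anchored to the replicate experiment, re-applying
    the filter with the same replicate matrix is a no-op. Returns the
    filtered matrix and an annotation frame recording each retained feature's
    technical variance.
    """
    if tech.shape[1] < 2:
        raise ValueError("technical-replicate matrix needs >= 2 columns")
    missing = expr.index.difference(tech.index)
    if len(missing) > 0:
        raise ValueError(
            f"features absent from the technical-replicate matrix: {list(missing[:5])}"
        )
    if not 0.0 <= top_frac <= 1.0:
        raise ValueError("top_frac must be in [0, 1]")
    tv_all = tech.var(axis=1, ddof=1)
    tv = tv_all.loc[expr.index]
    if top_frac == 0.0:
        keep = np.ones(len(expr), dtype=bool)
    else:
        cutoff = tv_all.quantile(1.0 - top_frac)
        keep = (tv < cutoff).to_numpy()
    out = expr.loc[keep]
    ann = pd.DataFrame({"tech_variance": tv[keep]}, index=out.index)
    return out, ann


def _anova_r2(scores: np.ndarray, batches: np.ndarray) -> float:
    """One-way ANOVA R2 (between-group SS over total SS) of scores on batch."""
    grand = scores.mean()
    ss_tot = float(((scores - grand) ** 2).sum())
    if ss_tot == 0.0:
        return 0.0
    ss_between = 0.0
    for b in np.unique(batches):
        grp = scores[batches == b]
        ss_between += len(grp) * (grp.mean() - grand) ** 2
    return float(ss_between / ss_tot)


def remove_batch_components(
    expr: pd.DataFrame,
    batches,
    n_examine: int = 10,
    n_remove: int = 2,
) -> BatchCorrectionResult:
    """Remove the principal components most associated with batch.

    The feature-centred matrix is decomposed by SVD; sample-space component
    scores are scored against batch by one-way-ANOVA R2 over the first
    ``n_examine`` components, and the ``n_remove`` highest-R2 components are
    subtracted (reconstruction without them). Feature means are unchanged,
    so total variance drops by exactly the variance of the removed
    components.
    """
    batches = np.asarray(batches)
    if len(batches) != expr.shape[1]:
        raise ValueError("batch vector length does not match sample count")
    if len(np.unique(batches)) < 2:
        raise ValueError("batch association undefined with a single batch")
    n = expr.shape[1]
    if not 1 <= n_remove <= n_examine <= n - 1:
        raise ValueError("need 1 <= n_remove <= n_examine <= n_samples - 1")

    X = expr.to_numpy(dtype=float)
    row_means = X.mean(axis=1, keepdims=True)
    Xc = X - row_means
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)

    n_examine = min(n_examine, len(s))
    r2 = np.array([_anova_r2(s[k] * Vt[k], batches) for k in range(n_examine)])
    order = np.argsort(r2)[::-1]
    removed = np.sort(order[:n_remove])

    recon = Xc.copy()
    for k in removed:
        recon -= s[k] * np.outer(U[:, k], Vt[k])
    corrected = pd.DataFrame(recon + row_means, index=expr.index, columns=expr.columns)

    total = float((s**2).sum())
    captured = float((s[:n_examine] ** 2).sum() / total) if total > 0 else 0.0
    return BatchCorrectionResult(
        corrected=corrected,
        removed_component_indices=[int(k) + 1 for k in removed],
        batch_r2_per_pc=r2,
        variance_captured=captured,
        removed_directions=Vt[removed],
        removed_loadings=U[:, removed],
        feature_means=row_means,
    )
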