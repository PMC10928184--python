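"""Sample-level cohort structure: PC-based hierarchical clustering and
discriminant analysis of principal components (DAPC).

DAPC reduces the expression matrix by PCA, then runs a linear discriminant
analysis on the cohort labels; posterior cohort memberships come from the
discriminant-space Gaussian model with equal priors.  The number of PCs to
retain is chosen with the a-score: observed reassignment proportion minus
the mean reassignment proportion under random relabelings, penalizing the
overfitting that inflates reassignment as PCs approach the sample count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .exceptions import DegenerateDataError

__all__ = ["DapcResult", "sample_dendrogram", "dapc", "optimize_a_score"]


@dataclass
class DapcResult:
    n_pcs_retained: int
    axes: pd.DataFrame            # per-sample discriminant coordinates
    posterior: pd.DataFrame       # samples x cohorts, rows sum to 1
    reassignment: pd.DataFrame    # prior cohorts x assigned cohorts (counts)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.reassignment.to_numpy()) / self.reassignment.to_numpy().sum())


def _standardize_genes(expr: pd.DataFrame) -> np.ndarray:
    arr = expr.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (arr - mu) / sd


def _pca_scores(expr: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Sample scores and explained-variance ratios from gene-standardized PCA."""
    z = _standardize_genes(expr).T  # samples x genes
    z = z - z.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    var = s**2
    ratio = var / var.sum() if var.sum() > 0 else var
    return u * s, ratio


def sample_dendrogram(expr: pd.DataFrame, var_explained: float = 0.80) -> np.ndarray:
    """Ward linkage of samples in the top-PC space (PCs covering
    >= ``var_explained`` of the variance)."""
    if expr.shape[1] < 3:
        raise DegenerateDataError("need >= 3 samples")
    scores, ratio = _pca_scores(expr)
    n_pcs = int(np.searchsorted(np.cumsum(ratio), var_explained) + 1)
    n_pcs = min(n_pcs, scores.shape[1])
    return linkage(scores[:, :n_pcs], method="ward")


def dapc(expr: pd.DataFrame, labels: pd.Series, n_pcs: int) -> DapcResult:
    """PCA reduction to ``n_pcs`` followed by LDA on cohort labels."""
    labels = labels.loc[expr.columns]
    counts = labels.value_counts()
    if counts.size < 2:
        raise DegenerateDataError("DAPC needs >= 2 cohorts")
    if (counts < 2).any():
        small = list(counts.index[counts < 2])
        raise DegenerateDataError(f"cohort(s) with < 2 samples: {small}")
    n_samples, n_groups = expr.shape[1], counts.size
    if n_pcs >= n_samples - n_groups:
        raise DegenerateDataError(
            f"n_pcs={n_pcs} must be < n_samples - n_cohorts = {n_samples - n_groups}"
        )
    scores, _ = _pca_scores(expr)
    x = scores[:, :n_pcs]
    groups = sorted(counts.index)
    lda = LinearDiscriminantAnalysis(priors=np.full(n_groups, 1.0 / n_groups))
    lda.fit(x, labels.to_numpy())
    post = lda.predict_proba(x)
    axes = lda.transform(x)
    assigned = np.asarray(lda.classes_)[np.argmax(post, axis=1)]
    reassign = pd.crosstab(
        pd.Categorical(labels, categories=groups),
        pd.Categorical(assigned, categories=groups),
        dropna=False,
    )
    reassign.index = pd.Index(groups, name="prior")
    reassign.columns = pd.Index(groups, name="assigned")
    return DapcResult(
        n_pcs_retained=n_pcs,
        axes=pd.DataFrame(
            axes, index=expr.columns, columns=[f"LD{i + 1}" for i in range(axes.shape[1])]
        ),
        posterior=pd.DataFrame(post, index=expr.columns, columns=lda.classes_),
        reassignment=reassign,
    )


def optimize_a_score(
    expr: pd.DataFrame,
    labels: pd.Series,
    n_pcs_grid,
    n_label_shuffles: int = 10,
    seed: int = 0,
) -> tuple[int, pd.Series]:
    """Pick the PC count maximizing the a-score.

    a-score(n_pcs) = observed reassignment proportion - mean reassignment
    proportion over ``n_label_shuffles`` random relabelings at the same
    settings.  Returns (best n_pcs, a-score per grid value).
    """
    grid = list(n_pcs_grid)
    if not grid:
        raise DegenerateDataError("empty n_pcs grid")
    labels = labels.loc[expr.columns]
    rng = np.random.default_rng(seed)
    shuffles = [
        pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        for _ in range(n_label_shuffles)
    ]
    scores = {}
    for n_pcs in grid:
        obs = dapc(expr, labels, n_pcs).accuracy
        null = [dapc(expr, sh, n_pcs).accuracy for sh in shuffles]
        scores[n_pcs] = obs - float(np.mean(null))
    curve = pd.Series(scores, name="a_score")
    return int(curve.idxmax()), curve
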