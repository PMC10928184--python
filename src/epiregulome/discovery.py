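"""Per-cohort gene coexpression module discovery.

Workflow: Spearman dissimilarity -> signed soft-threshold adjacency (power
6) -> Ward clustering with the number of clusters K chosen at the inflection
point of the variance-explained curve R^2(K) -> leave-one-out stability
bootstrapping over samples -> removal of the low-cohesion "junk" residue ->
consensus clustering of the co-clustering similarity matrix -> splitting of
each module into over-/under-expressed (o/u) submodules by (anti-)correlation
with the module eigengene.

Modules are only assembled in cohorts with more than 20 samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .exceptions import CohortSizeError, DegenerateDataError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModule",
    "ModuleSet",
    "spearman_dissimilarity",
    "soft_adjacency",
    "select_k",
    "loo_stability",
    "remove_junk",
    "consensus_modules",
    "split_ou",
    "discover_modules",
]

MIN_COHORT_SAMPLES = 21  # discovery gate: cohorts must have > 20 samples


@dataclass(frozen=True)
class GeneModule:
    """A final (sub)module: id ``{cohort}.{index}.{o|u}``, member genes, and
    per-gene stability (mean co-clustering fraction with the other members
    across leave-one-out iterations)."""

    module_id: str
    cohort: str
    genes: tuple[str, ...]
    stability: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.genes) < 1:
            raise ValueError(f"module {self.module_id}: empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"module {self.module_id}: duplicate genes")

    @property
    def suffix(self) -> str:
        return self.module_id.rsplit(".", 1)[-1]

    @property
    def gene_set(self) -> set[str]:
        return set(self.genes)


@dataclass
class ModuleSet:
    """All modules discovered in one cohort plus selection diagnostics."""

    cohort: str
    modules: list[GeneModule]
    k_selected: int
    r2_curve: pd.Series
    junk_genes: tuple[str, ...] = ()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        members = [g for m in self.modules for g in m.genes]
        if len(members) != len(set(members)):
            raise ValueError("a gene appears in two modules of one cohort")
        if set(self.junk_genes) & set(members):
            raise ValueError("junk genes overlap module members")

    def __iter__(self):
        return iter(self.modules)

    def gene_sets(self) -> dict[str, set[str]]:
        return {m.module_id: m.gene_set for m in self.modules}


# ---------------------------------------------------------------------------
# distance / adjacency kernels


def _spearman_corr(arr: np.ndarray) -> np.ndarray:
    """Spearman correlation between rows (average ranks for ties)."""
    ranks = rankdata(arr, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    sd = np.sqrt((ranks**2).sum(axis=1))
    if (sd == 0).any():
        raise DegenerateDataError("constant gene")
    ranks /= sd[:, None]
    rho = ranks @ ranks.T
    return np.clip(rho, -1.0, 1.0)


def spearman_dissimilarity(expr: pd.DataFrame) -> pd.DataFrame:
    """1 - Spearman rank correlation for all gene pairs; range [0, 2]."""
    if expr.shape[1] < 4:
        raise DegenerateDataError("need >= 4 samples")
    arr = expr.to_numpy(dtype=float)
    const = np.flatnonzero(np.ptp(arr, axis=1) == 0)
    if const.size:
        names = [expr.index[i] for i in const[:5]]
        raise DegenerateDataError(f"constant gene(s): {names}")
    d = 1.0 - _spearman_corr(arr)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=expr.index, columns=expr.index)


def soft_adjacency(D: pd.DataFrame | np.ndarray, beta: float = 6.0) -> pd.DataFrame | np.ndarray:
    """Signed soft-threshold adjacency A = ((1 + rho)/2)^beta, rho = 1 - D.

    The signed form keeps anti-correlated genes far apart, which the later
    o/u split relies on.  Clustering uses distance 1 - A.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    rho = 1.0 - (D.to_numpy() if isinstance(D, pd.DataFrame) else np.asarray(D, float))
    a = ((1.0 + rho) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    if isinstance(D, pd.DataFrame):
        return pd.DataFrame(a, index=D.index, columns=D.columns)
    return a


# ---------------------------------------------------------------------------
# K selection


def _ward_linkage(dist: np.ndarray) -> np.ndarray:
    return linkage(squareform(dist, checks=False), method="ward")


def _mds_embedding(dist: np.ndarray) -> np.ndarray:
    """Classical MDS coordinates preserving squared distances (nonnegative
    eigenvalue dimensions only)."""
    n = dist.shape[0]
    d2 = dist**2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2.0)
    keep = vals > max(1e-10, 1e-9 * vals.max() if vals.size else 0.0)
    return vecs[:, keep] * np.sqrt(vals[keep])


def _r2_curve(coords: np.ndarray, labels_by_k: np.ndarray, ks: np.ndarray) -> np.ndarray:
    """R^2(K) = 1 - within-cluster SS / total SS on the embedded coordinates."""
    center = coords.mean(axis=0)
    tss = float(((coords - center) ** 2).sum())
    if tss == 0:
        return np.ones_like(ks, dtype=float)
    sq = (coords**2).sum(axis=1)
    r2 = np.empty(len(ks))
    for i, k in enumerate(ks):
        lab = labels_by_k[:, i]
        nk = np.bincount(lab)
        sums = np.zeros((nk.size, coords.shape[1]))
        np.add.at(sums, lab, coords)
        # WSS = sum |x|^2 - sum_k |sum_x|^2 / n_k
        wss = float(sq.sum() - ((sums**2).sum(axis=1) / np.maximum(nk, 1)).sum())
        r2[i] = 1.0 - max(wss, 0.0) / tss
    return r2


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or y.size < 3:
        return y
    w = min(window, y.size if y.size % 2 else y.size - 1)
    if w % 2 == 0:
        w -= 1
    if w < 3:
        return y
    pad = w // 2
    yp = np.pad(y, pad, mode="edge")
    kernel = np.ones(w) / w
    return np.convolve(yp, kernel, mode="valid")


def select_k(
    dist: pd.DataFrame | np.ndarray,
    k_min: int = 1,
    k_max: int = 200,
    smooth_window: int = 1,
    link: np.ndarray | None = None,
) -> tuple[int, pd.Series]:
    """Choose K at the inflection of the variance-explained curve.

    The Ward tree is cut at every K in [k_min, k_max]; R^2(K) is evaluated on
    a classical-MDS embedding of the distance matrix; K is the interior point
    maximizing the absolute discrete second difference of the (smoothed)
    curve.  A perfectly linear curve has no inflection and falls back to
    ``k_min`` with a warning.
    """
    d = dist.to_numpy() if isinstance(dist, pd.DataFrame) else np.asarray(dist, float)
    n = d.shape[0]
    if k_max > n:
        logger.warning("k_max=%d clipped to n_genes=%d", k_max, n)
        k_max = n
    ks = np.arange(max(1, k_min), k_max + 1)
    if ks.size < 3:
        raise DegenerateDataError("need >= 3 distinct K values to locate an inflection")
    if link is None:
        link = _ward_linkage(d)
    labels = cut_tree(link, n_clusters=ks)
    # scipy's cut_tree returns a single cluster for K = n; fix up that column
    for i, k in enumerate(ks):
        if k == n:
            labels[:, i] = np.arange(n)
    coords = _mds_embedding(d)
    r2 = _r2_curve(coords, labels, ks)
    sm = _smooth(r2, smooth_window)
    d2 = sm[2:] - 2.0 * sm[1:-1] + sm[:-2]
    curve = pd.Series(r2, index=ks, name="r2")
    if np.max(np.abs(d2)) < 1e-12:
        logger.warning("R^2 curve has no inflection; falling back to k_min=%d", ks[0])
        return int(ks[0]), curve
    k_sel = int(ks[1:-1][int(np.argmax(np.abs(d2)))])
    return k_sel, curve


# ---------------------------------------------------------------------------
# leave-one-out stability


def _cluster_once(
    arr: np.ndarray, beta: float, k_fixed: int | None, k_max: int
) -> tuple[np.ndarray, np.ndarray]:
    """dissimilarity -> adjacency -> Ward -> K selection; returns (labels, A)."""
    rho = _spearman_corr(arr)
    a = ((1.0 + rho) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    dist = 1.0 - a
    np.fill_diagonal(dist, 0.0)
    link = _ward_linkage(dist)
    if k_fixed is None:
        k, _ = select_k(dist, k_max=k_max, link=link)
    else:
        k = k_fixed
    labels = cut_tree(link, n_clusters=k).ravel()
    return labels, a


def _junk_cluster(labels: np.ndarray, adj: np.ndarray, cohesion_floor: bool) -> int | None:
    """Index of the per-iteration junk cluster: lowest mean intramodular
    adjacency.  With the cohesion floor on (default), only flagged if its
    cohesion is below the matrix-wide mean adjacency."""
    ks = np.unique(labels)
    cohesion = np.empty(ks.size)
    for i, k in enumerate(ks):
        idx = np.flatnonzero(labels == k)
        if idx.size < 2:
            cohesion[i] = 0.0
        else:
            sub = adj[np.ix_(idx, idx)]
            cohesion[i] = (sub.sum() - idx.size) / (idx.size * (idx.size - 1))
    j = int(np.argmin(cohesion))
    if cohesion_floor:
        n = adj.shape[0]
        overall = (adj.sum() - n) / (n * (n - 1))
        if cohesion[j] >= overall:
            return None
    return int(ks[j])


def loo_stability(
    expr: pd.DataFrame,
    beta: float = 6.0,
    k_policy: str = "per_iteration",
    k_max: int = 200,
    cohesion_floor: bool = True,
) -> tuple[pd.DataFrame, pd.Series, int]:
    """Leave-one-out co-clustering similarity.

    One iteration per sample: drop it, re-run the full dissimilarity ->
    adjacency -> Ward -> K workflow, record co-cluster memberships and the
    per-iteration junk cluster.  Returns (S, junk_fraction per gene, n_iter).
    ``k_policy``: "per_iteration" re-selects K each time; "fixed" reuses the
    full-data K.
    """
    if expr.shape[1] < 5:
        raise DegenerateDataError("leave-one-out needs >= 5 samples")
    if k_policy not in ("per_iteration", "fixed"):
        raise ValueError("k_policy must be 'per_iteration' or 'fixed'")
    arr = expr.to_numpy(dtype=float)
    n_genes, n_samples = arr.shape
    k_fixed = None
    if k_policy == "fixed":
        k_fixed, _ = _full_data_k(arr, beta, k_max)

    co = np.zeros((n_genes, n_genes))
    valid = np.zeros((n_genes, n_genes))
    junk_counts = np.zeros(n_genes)
    junk_iters = np.zeros(n_genes)
    ok_genes = np.ones(n_genes, dtype=bool)

    for s in range(n_samples):
        sub = np.delete(arr, s, axis=1)
        alive = np.flatnonzero(np.ptp(sub, axis=1) > 0)
        if alive.size < n_genes:
            dropped = np.setdiff1d(np.arange(n_genes), alive)
            ok_genes[dropped] = False
            logger.warning(
                "iteration %d: %d constant gene(s) excluded", s, dropped.size
            )
        labels, adj = _cluster_once(sub[alive], beta, k_fixed, k_max)
        same = labels[:, None] == labels[None, :]
        ix = np.ix_(alive, alive)
        co[ix] += same
        valid[ix] += 1.0
        jc = _junk_cluster(labels, adj, cohesion_floor)
        junk_iters[alive] += 1.0
        if jc is not None:
            junk_counts[alive[labels == jc]] += 1.0

    keep = ok_genes & (valid.diagonal() > 0)
    idx = np.flatnonzero(keep)
    with np.errstate(invalid="ignore", divide="ignore"):
        s_mat = np.where(valid > 0, co / np.maximum(valid, 1), 0.0)
    s_mat = s_mat[np.ix_(idx, idx)]
    np.fill_diagonal(s_mat, 1.0)
    genes = [expr.index[i] for i in idx]
    s_df = pd.DataFrame(s_mat, index=genes, columns=genes)
    junk_frac = pd.Series(
        junk_counts[idx] / np.maximum(junk_iters[idx], 1.0), index=genes, name="junk_fraction"
    )
    return s_df, junk_frac, n_samples


def _full_data_k(arr: np.ndarray, beta: float, k_max: int) -> tuple[int, pd.Series]:
    rho = _spearman_corr(arr)
    a = ((1.0 + rho) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    dist = 1.0 - a
    np.fill_diagonal(dist, 0.0)
    return select_k(dist, k_max=k_max)


def remove_junk(junk_frac: pd.Series, junk_fraction: float = 0.50) -> list[str]:
    """Genes sitting in the per-iteration junk cluster in >= ``junk_fraction``
    of iterations (inclusive threshold)."""
    junk = [g for g, f in junk_frac.items() if f >= junk_fraction]
    if len(junk) == len(junk_frac):
        raise DegenerateDataError("every gene flagged junk: degenerate data")
    return junk


def consensus_modules(
    s_matrix: pd.DataFrame, k_max: int = 200
) -> tuple[pd.Series, int, pd.Series]:
    """Ward clustering of non-junk genes on distance 1 - S.

    Returns (gene -> cluster label, K, R^2 curve)."""
    if s_matrix.shape[0] < 2:
        raise DegenerateDataError("need >= 2 non-junk genes")
    dist = 1.0 - s_matrix.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = _ward_linkage(dist)
    k, curve = select_k(dist, k_max=k_max, link=link)
    labels = cut_tree(link, n_clusters=k).ravel()
    return pd.Series(labels, index=s_matrix.index, name="cluster"), k, curve


# ---------------------------------------------------------------------------
# o/u splitting


def _eigengene_scores(sub: np.ndarray) -> np.ndarray:
    """First-PC sample scores of the gene-standardized submatrix, sign-aligned
    with the mean member profile, unit variance."""
    z = sub - sub.mean(axis=1, keepdims=True)
    sd = z.std(axis=1)
    sd[sd == 0] = 1.0
    z /= sd[:, None]
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    scores = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(scores, mean_profile) < 0:
        scores = -scores
    s = scores.std()
    return scores / (s if s > 0 else 1.0)


def split_ou(
    genes: tuple[str, ...] | list[str],
    expr_disease: pd.DataFrame,
    expr_control: pd.DataFrame,
    cohort: str,
    index: int,
    stability: dict[str, float] | None = None,
) -> list[GeneModule]:
    """Split a preliminary module into o/u submodules.

    Genes are partitioned by the sign of their correlation with the module
    eigengene (computed on disease samples); each part is labeled ``o`` if
    its mean disease-minus-control log2 expression is positive, else ``u``.
    If both parts receive the same suffix they are merged back (ids must be
    unique) with a warning.
    """
    if expr_control.shape[1] == 0:
        raise DegenerateDataError(f"cohort {cohort}: no control samples")
    genes = list(genes)
    sub = expr_disease.loc[genes].to_numpy(dtype=float)
    if len(genes) == 1:
        parts = [genes]
    else:
        eig = _eigengene_scores(sub)
        z = sub - sub.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(z, axis=1) * np.linalg.norm(eig - eig.mean())
        denom[denom == 0] = 1.0
        corr = (z @ (eig - eig.mean())) / denom
        pos = [g for g, c in zip(genes, corr) if c >= 0]
        neg = [g for g, c in zip(genes, corr) if c < 0]
        parts = [p for p in (pos, neg) if p]

    fc = (
        expr_disease.loc[genes].mean(axis=1) - expr_control.loc[genes].mean(axis=1)
    )  # per-gene log2 disease - control

    labeled: list[tuple[str, list[str]]] = []
    for part in parts:
        suffix = "o" if float(fc.loc[part].mean()) > 0 else "u"
        labeled.append((suffix, part))
    if len(labeled) == 2 and labeled[0][0] == labeled[1][0]:
        warnings.warn(
            f"module {cohort}.{index}: both halves {labeled[0][0]!r}-labeled; merging",
            stacklevel=2,
        )
        labeled = [(labeled[0][0], labeled[0][1] + labeled[1][1])]

    out = []
    for suffix, part in labeled:
        stab = tuple(float(stability.get(g, np.nan)) for g in part) if stability else ()
        out.append(
            GeneModule(
                module_id=f"{cohort}.{index}.{suffix}",
                cohort=cohort,
                genes=tuple(part),
                stability=stab,
            )
        )
    return out


# ---------------------------------------------------------------------------
# full per-cohort pipeline


def discover_modules(
    expr_disease: pd.DataFrame,
    expr_control: pd.DataFrame,
    cohort: str,
    beta: float = 6.0,
    k_max: int = 200,
    junk_fraction: float = 0.50,
    mad_min: float = 0.25,
    k_policy: str = "per_iteration",
    cohesion_floor: bool = True,
    min_samples: int = MIN_COHORT_SAMPLES,
) -> ModuleSet:
    """Run the complete discovery workflow for one cohort.

    ``expr_disease`` drives network construction and stability; controls are
    used only for the o/u labeling.  Cohorts with <= 20 disease samples are
    refused.
    """
    n = expr_disease.shape[1]
    if n < min_samples:
        raise CohortSizeError(
            f"cohort {cohort}: {n} samples; module discovery requires more than "
            f"{min_samples - 1}"
        )
    from .preprocess import mad_filter

    kept = mad_filter(expr_disease, mad_min=mad_min)
    if len(kept) < 3:
        raise DegenerateDataError(f"cohort {cohort}: <3 genes pass the MAD filter")
    expr_d = expr_disease.loc[kept]

    s_mat, junk_frac, n_iter = loo_stability(
        expr_d, beta=beta, k_policy=k_policy, k_max=k_max, cohesion_floor=cohesion_floor
    )
    junk = remove_junk(junk_frac, junk_fraction=junk_fraction)
    non_junk = [g for g in s_mat.index if g not in set(junk)]
    labels, k_sel, r2_curve = consensus_modules(s_mat.loc[non_junk, non_junk], k_max=k_max)

    # per-gene stability = mean co-clustering with the other members
    modules: list[GeneModule] = []
    # deterministic module numbering: by descending size, ties by first gene id
    clusters = labels.groupby(labels).groups
    ordered = sorted(
        clusters.items(), key=lambda kv: (-len(kv[1]), sorted(kv[1])[0])
    )
    for rank, (_, gene_index) in enumerate(ordered, start=1):
        member_genes = sorted(gene_index)
        sub_s = s_mat.loc[member_genes, member_genes].to_numpy()
        m = len(member_genes)
        if m > 1:
            stab_vals = (sub_s.sum(axis=1) - 1.0) / (m - 1)
        else:
            stab_vals = np.ones(1)
        stab = dict(zip(member_genes, stab_vals))
        modules.extend(
            split_ou(member_genes, expr_d, expr_control, cohort, rank, stability=stab)
        )

    return ModuleSet(
        cohort=cohort,
        modules=modules,
        k_selected=k_sel,
        r2_curve=r2_curve,
        junk_genes=tuple(junk),
        provenance={
            "n_samples": n,
            "n_iterations": n_iter,
            "beta": beta,
            "k_policy": k_policy,
            "mad_min": mad_min,
            "n_genes_mad": len(kept),
            "n_junk": len(junk),
        },
    )
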