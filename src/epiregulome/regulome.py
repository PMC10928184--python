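"""Cross-cohort regulome integration.

Modules from all cohorts are compared by gene-content overlap with the
inclusion index |x n y| / min(|x|, |y|), clustered (Ward, silhouette-chosen
K), and each resulting cluster ("regulome") is classified by its activity
pattern: constitutive (no change disease vs control), enhanced (conserved in
controls but with significantly increased coexpression in disease),
activated (coexpression present and significant only in disease), or
pathology-specific (confined to a single cohort yet differentially
coexpressed there).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .coex import ConservationCall, CoexStat
from .exceptions import DegenerateDataError

logger = logging.getLogger(__name__)

__all__ = [
    "Regulome",
    "inclusion_index",
    "cluster_modules",
    "intersect_genes",
    "classify_regulome",
    "build_regulomes",
]

CLASSES = ("constitutive", "enhanced", "activated", "pathology_specific")


@dataclass
class Regulome:
    regulome_id: str
    member_modules: list[str]          # module ids
    member_cohorts: dict[str, str]     # module id -> cohort
    intersect_genes: set[str] = field(default_factory=set)
    label: str = ""
    shared_regulators: list[str] = field(default_factory=list)


def inclusion_index(x, y) -> float:
    """|x n y| / min(|x|, |y|); symmetric, in [0, 1]."""
    xs, ys = set(x), set(y)
    if not xs or not ys:
        raise DegenerateDataError("inclusion index undefined for empty sets")
    return len(xs & ys) / min(len(xs), len(ys))


def cluster_modules(
    module_genes: dict[str, set[str]],
    k_cap: int = 40,
) -> dict[str, int]:
    """Partition modules into regulomes.

    Distance = 1 - inclusion index; Ward clustering; K maximizes the mean
    silhouette over K = 2..min(n_modules - 1, k_cap).  If every pairwise
    distance is 1 (mutually disjoint modules) the silhouette is degenerate
    and the partition falls back to K = n singletons with a warning.
    Returns module id -> cluster label.
    """
    ids = sorted(module_genes)
    n = len(ids)
    if n < 3:
        raise DegenerateDataError("need >= 3 modules to cluster")
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - inclusion_index(module_genes[ids[i]], module_genes[ids[j]])
            dist[i, j] = dist[j, i] = d
    if np.all(dist[np.triu_indices(n, 1)] >= 1.0 - 1e-12):
        logger.warning("all modules mutually disjoint; falling back to K = n singletons")
        return {mid: i for i, mid in enumerate(ids)}
    link = linkage(squareform(dist, checks=False), method="ward")
    best_k, best_score = None, -np.inf
    for k in range(2, min(n - 1, k_cap) + 1):
        labels = cut_tree(link, n_clusters=k).ravel()
        if len(np.unique(labels)) < 2:
            continue
        try:
            score = silhouette_score(dist, labels, metric="precomputed")
        except ValueError:
            continue
        if score > best_score + 1e-12:
            best_k, best_score = k, score
    if best_k is None:
        logger.warning("silhouette degenerate; falling back to K = n singletons")
        return {mid: i for i, mid in enumerate(ids)}
    labels = cut_tree(link, n_clusters=best_k).ravel()
    return {mid: int(lab) for mid, lab in zip(ids, labels)}


def intersect_genes(
    member_genes: dict[str, set[str]],
    member_cohorts: dict[str, str],
) -> set[str]:
    """Genes occurring in >= 1 member module of every cohort represented in
    the regulome; single-cohort regulomes return the union of members."""
    cohorts = set(member_cohorts.values())
    union_by_cohort = {
        c: set().union(*(member_genes[m] for m, cc in member_cohorts.items() if cc == c))
        for c in cohorts
    }
    if len(cohorts) == 1:
        return next(iter(union_by_cohort.values()))
    return set.intersection(*union_by_cohort.values())


def classify_regulome(
    member_modules: list[str],
    member_cohorts: dict[str, str],
    coex_stats: dict[str, CoexStat],
    conservation: dict[str, list[ConservationCall]],
    all_module_genes: dict[str, set[str]] | None = None,
    module_cohorts_all: dict[str, str] | None = None,
    alpha: float = 0.05,
    cross_cohort_ii_min: float = 0.3,
) -> str:
    """Assign one of the four activity classes.

    Precedence: pathology_specific -> activated -> enhanced -> constitutive.
    ``conservation`` maps module id to its conservation calls in *control*
    cohorts.  ``all_module_genes`` / ``module_cohorts_all`` (every module of
    the study) enable the cross-cohort inclusion check for single-cohort
    regulomes.
    """
    missing = [m for m in member_modules if m not in coex_stats]
    if missing:
        raise DegenerateDataError(f"missing coexpression statistics for module(s) {missing}")
    dc_sig = {m: coex_stats[m].p_empirical < alpha for m in member_modules}
    dc_sig_pos = {
        m: dc_sig[m] and coex_stats[m].delta_r2 > 0 for m in member_modules
    }
    conserved_in_controls = {
        m: any(c.conserved for c in conservation.get(m, [])) for m in member_modules
    }
    any_sig = any(dc_sig.values())

    # rule 1: pathology-specific
    single_cohort = len(set(member_cohorts.values())) == 1
    isolated = single_cohort
    if single_cohort and all_module_genes and module_cohorts_all:
        cohort = next(iter(set(member_cohorts.values())))
        max_ii = 0.0
        for m in member_modules:
            for other, genes in all_module_genes.items():
                if module_cohorts_all.get(other) == cohort or other in member_modules:
                    continue
                max_ii = max(max_ii, inclusion_index(all_module_genes[m], genes))
        isolated = max_ii < cross_cohort_ii_min
    if single_cohort and isolated and any_sig:
        return "pathology_specific"
    # rule 2: activated
    if any_sig and not any(conserved_in_controls.values()):
        return "activated"
    # rule 3: enhanced
    if any(dc_sig_pos.values()) and any(conserved_in_controls.values()):
        return "enhanced"
    return "constitutive"


def build_regulomes(
    module_genes: dict[str, set[str]],
    module_cohorts: dict[str, str],
    coex_stats: dict[str, CoexStat],
    conservation: dict[str, list[ConservationCall]],
    predictions: pd.DataFrame | None = None,
    alpha: float = 0.05,
    cross_cohort_ii_min: float = 0.3,
    k_cap: int = 40,
) -> list[Regulome]:
    """Cluster + intersect + classify in one pass; optionally attach shared
    regulators (regulators significant for >= 2 member modules)."""
    labels = cluster_modules(module_genes, k_cap=k_cap)
    regulomes: list[Regulome] = []
    for lab in sorted(set(labels.values())):
        members = sorted(m for m, l in labels.items() if l == lab)
        cohorts = {m: module_cohorts[m] for m in members}
        reg = Regulome(
            regulome_id=f"R{lab + 1}",
            member_modules=members,
            member_cohorts=cohorts,
        )
        reg.intersect_genes = intersect_genes(
            {m: module_genes[m] for m in members}, cohorts
        )
        reg.label = classify_regulome(
            members,
            cohorts,
            coex_stats,
            conservation,
            all_module_genes=module_genes,
            module_cohorts_all=module_cohorts,
            alpha=alpha,
            cross_cohort_ii_min=cross_cohort_ii_min,
        )
        if predictions is not None and not predictions.empty:
            sig = predictions[
                (predictions["module_id"].isin(members)) & (predictions["fdr"] < alpha)
            ]
            counts = sig.groupby("regulator_id")["module_id"].nunique()
            reg.shared_regulators = sorted(counts.index[counts >= 2])
        regulomes.append(reg)
    return regulomes
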