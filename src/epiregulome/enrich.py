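"""Hypergeometric gene-set enrichment with Benjamini-Hochberg FDR.

All expressed genes form the background universe.  The upper-tail p-value is
accumulated in log space for numerical stability; FDR is applied within a
collection across every (query, set) test of a family, reflecting the total
number of enrichment tests performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateDataError

__all__ = ["EnrichmentResult", "hypergeom_p", "bh_fdr", "annotate"]


@dataclass(frozen=True)
class EnrichmentResult:
    query_id: str
    set_name: str
    collection: str
    overlap: int
    query_size: int
    set_size: int
    universe_size: int
    p: float
    fdr: float


def _log_comb(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    n, k = np.asarray(n, float), np.asarray(k, float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_p(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn).

    ``k`` = overlap, ``n`` = query size, ``K`` = gene-set size, ``N`` =
    universe size.  Computed by log-space summation over the support.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    i = np.arange(k, min(n, K) + 1)
    log_terms = _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def bh_fdr(p: np.ndarray | list[float] | pd.Series) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values with enforced monotonicity."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if (arr <= 0).any() or (arr > 1).any() or np.isnan(arr).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def annotate(
    queries: dict[str, set[str]] | set[str],
    collections: dict[str, dict[str, set[str]]],
    universe: set[str] | list[str],
) -> pd.DataFrame:
    """Enrichment table for one or more query gene sets against collections.

    ``collections`` maps collection name -> {set name -> members}.  Genes
    outside the universe are dropped (with a warning); FDR is computed within
    each collection across all (query, set) pairs.
    """
    if isinstance(queries, (set, frozenset, list, tuple)):
        queries = {"query": set(queries)}
    uni = set(universe)
    N = len(uni)
    if N == 0:
        raise DegenerateDataError("empty universe")
    rows = []
    for coll_name, sets in collections.items():
        if not sets:
            raise DegenerateDataError(f"empty collection {coll_name!r}")
        for query_id, query in queries.items():
            q = set(query) & uni
            if len(q) < len(set(query)):
                warnings.warn(
                    f"query {query_id!r}: {len(set(query)) - len(q)} gene(s) outside "
                    "the universe dropped",
                    stacklevel=2,
                )
            for set_name, members in sets.items():
                s = set(members) & uni
                if not s:
                    continue
                k = len(q & s)
                p = hypergeom_p(k, len(q), len(s), N)
                rows.append(
                    {
                        "query_id": query_id,
                        "set_name": set_name,
                        "collection": coll_name,
                        "overlap": k,
                        "query_size": len(q),
                        "set_size": len(s),
                        "universe_size": N,
                        "p": p,
                    }
                )
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(fdr=pd.Series(dtype=float))
    out["fdr"] = np.nan
    for coll_name, idx in out.groupby("collection").groups.items():
        out.loc[idx, "fdr"] = bh_fdr(out.loc[idx, "p"].to_numpy())
    return out.sort_values(["collection", "query_id", "p"], kind="stable").reset_index(
        drop=True
    )
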