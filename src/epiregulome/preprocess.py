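"""Raw gene counts -> normalized, variance-filtered log2 expression.

Steps mirror the standard bulk RNA-seq entry pipeline: a per-cohort
low-expression filter, weighted trimmed-mean-of-M-values (TMM) scaling
factors, the log2-CPM transform with a 0.5 pseudocount, and a median
absolute deviation variability filter applied before network construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import DegenerateDataError, SchemaError

__all__ = [
    "ExpressionStudy",
    "filter_low_expression",
    "tmm_normalize",
    "log_cpm",
    "mad_filter",
    "preprocess_study",
]


@dataclass
class ExpressionStudy:
    """Normalized log2 expression matrix plus per-sample metadata.

    ``expr`` is genes x samples on the log2-CPM scale; ``sample_meta`` is
    indexed by sample id and carries at least cohort and condition columns.
    ``provenance`` records the filters applied.
    """

    expr: pd.DataFrame
    sample_meta: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.expr.isna().any().any():
            raise SchemaError("expression matrix contains missing values")
        if self.expr.columns.duplicated().any():
            raise SchemaError("duplicate sample ids")
        missing = set(self.expr.columns) - set(self.sample_meta.index)
        if missing:
            raise SchemaError(f"samples without metadata: {sorted(missing)[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expr.index)

    def cohort_samples(self, cohort: str, condition: str | None = None) -> list[str]:
        m = self.sample_meta
        mask = m["cohort"] == cohort
        if condition is not None:
            mask &= m["condition"] == condition
        return [s for s in self.expr.columns if s in set(m.index[mask])]

    @property
    def cohorts(self) -> list[str]:
        return list(dict.fromkeys(self.sample_meta["cohort"]))


def _check_integer_counts(counts: pd.DataFrame) -> np.ndarray:
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr), atol=0):
            raise SchemaError("counts must be integers")
        arr = arr.astype(np.int64)
    if (arr < 0).any():
        raise SchemaError("counts must be nonnegative")
    return arr


def filter_low_expression(
    counts: pd.DataFrame,
    cohort_map: pd.Series | dict,
    min_count: int = 6,
    min_fraction: float = 0.20,
    per_cohort: str = "all",
) -> list[str]:
    """Genes expressed at >= ``min_count`` in >= ``min_fraction`` of samples.

    With ``per_cohort="all"`` (default) the rule must hold within every
    cohort; with ``"any"`` one qualifying cohort suffices.  Returns the
    retained gene ids in input order.
    """
    if per_cohort not in ("all", "any"):
        raise ValueError("per_cohort must be 'all' or 'any'")
    arr = _check_integer_counts(counts)
    cohort_map = pd.Series(cohort_map)
    missing = [s for s in counts.columns if s not in cohort_map.index]
    if missing:
        raise SchemaError(f"samples without cohort assignment: {missing[:5]}")
    groups = cohort_map.loc[counts.columns]
    keep = None
    for cohort in dict.fromkeys(groups):
        cols = np.flatnonzero((groups == cohort).to_numpy())
        if cols.size == 0:
            raise DegenerateDataError(f"empty cohort {cohort!r}")
        frac = (arr[:, cols] >= min_count).mean(axis=1)
        ok = frac >= min_fraction
        if keep is None:
            keep = ok
        else:
            keep = (keep & ok) if per_cohort == "all" else (keep | ok)
    assert keep is not None
    return [g for g, k in zip(counts.index, keep) if k]


def tmm_normalize(
    counts: pd.DataFrame,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
) -> pd.Series:
    """Weighted trimmed-mean-of-M-values scaling factors, one per sample.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean upper quartile.  Per sample, M (log2 expression
    ratio vs reference) and A (average log2 abundance) are computed over
    genes positive in both; M is trimmed two-sided by ``logratio_trim`` and
    A by ``abs_trim``; the factor is 2 to the inverse-variance-weighted mean
    of the surviving M values.  Factors are rescaled to have product 1.
    """
    arr = _check_integer_counts(counts).astype(float)
    n_genes, n_samples = arr.shape
    if n_samples < 2:
        raise DegenerateDataError("TMM needs >= 2 samples")
    lib = arr.sum(axis=0)
    if (lib == 0).any():
        bad = [s for s, tot in zip(counts.columns, lib) if tot == 0]
        raise DegenerateDataError(f"samples with zero total counts: {bad}")

    uq = np.quantile(arr, 0.75, axis=0) / lib
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    ref = arr[:, ref_j]
    n_ref = lib[ref_j]

    factors = np.ones(n_samples)
    for j in range(n_samples):
        obs = arr[:, j]
        n_obs = lib[j]
        ok = (obs > 0) & (ref > 0)
        if not ok.any():
            raise DegenerateDataError(
                f"no gene positive in both sample {counts.columns[j]!r} and reference"
            )
        o, r = obs[ok], ref[ok]
        m = np.log2((o / n_obs) / (r / n_ref))
        a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
        v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
        fin = np.isfinite(m) & np.isfinite(a)
        m, a, v = m[fin], a[fin], v[fin]
        if m.size == 0 or np.max(np.abs(m)) < 1e-6:
            continue
        n = m.size
        lo_m = np.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * abs_trim) + 1
        hi_a = n + 1 - lo_a
        rm = rankdata(m)
        ra = rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if keep.any():
            # inverse-variance weighted mean of the trimmed M values
            f = np.nansum(m[keep] / v[keep]) / np.nansum(1.0 / v[keep])
            if np.isfinite(f):
                factors[j] = 2.0**f
    # rescale: product 1 (equivalently geometric mean 1)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def log_cpm(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    offset: float = 0.5,
) -> pd.DataFrame:
    """log2 counts-per-million: log2((count + offset) / (libsize * factor + 1) * 1e6)."""
    arr = counts.to_numpy().astype(float)
    if (arr < 0).any():
        raise SchemaError("counts must be nonnegative")
    lib = arr.sum(axis=0)
    f = np.ones(arr.shape[1]) if factors is None else factors.loc[counts.columns].to_numpy()
    eff = lib * f + 1.0
    out = np.log2((arr + offset) / eff * 1e6)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def mad_filter(expr: pd.DataFrame, mad_min: float = 0.25) -> list[str]:
    """Genes whose raw median absolute deviation is >= ``mad_min`` (inclusive).

    The MAD is computed without the 1.4826 normal-consistency constant.
    """
    if expr.shape[1] < 3:
        raise DegenerateDataError("MAD filter needs >= 3 samples")
    arr = expr.to_numpy()
    med = np.median(arr, axis=1, keepdims=True)
    mad = np.median(np.abs(arr - med), axis=1)
    return [g for g, v in zip(expr.index, mad) if v >= mad_min]


def preprocess_study(
    counts: pd.DataFrame,
    sample_meta: pd.DataFrame,
    min_count: int = 6,
    min_fraction: float = 0.20,
    per_cohort: str = "all",
) -> ExpressionStudy:
    """Low-expression filter + TMM + log2-CPM in one step.

    The MAD variability filter is applied later, per cohort, at module
    discovery time.
    """
    meta = sample_meta.copy()
    if "sample_id" in meta.columns and meta.index.name is None and not meta.index.equals(
        pd.Index(meta["sample_id"])
    ):
        meta = meta.set_index("sample_id", drop=False)
    counts = counts[[s for s in counts.columns if s in set(meta.index)]]
    kept = filter_low_expression(
        counts, meta["cohort"], min_count=min_count, min_fraction=min_fraction,
        per_cohort=per_cohort,
    )
    filtered = counts.loc[kept]
    factors = tmm_normalize(filtered)
    expr = log_cpm(filtered, factors)
    prov = {
        "n_genes_in": int(counts.shape[0]),
        "n_genes_kept": len(kept),
        "min_count": min_count,
        "min_fraction": min_fraction,
        "per_cohort": per_cohort,
        "tmm_factors": {s: float(v) for s, v in factors.items()},
    }
    return ExpressionStudy(expr=expr, sample_meta=meta, provenance=prov)
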