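"""Differential coexpression, conservation, and eigengene-phenotype tests.

The module-level statistic is the median pairwise squared Spearman
correlation (R^2) of the module's genes.  Differential coexpression compares
disease vs control arms on the difference in median R^2 against a
label-permutation null (two-sided, +1-smoothed empirical p).  Conservation
asks whether a module's coexpression exceeds what random same-size gene sets
achieve in a target cohort (gene-resampling null).  Phenotype association is
an OLS of the module eigengene on a clinical covariate; age is added as a
covariate whenever the covariate is epilepsy duration, since duration and
age are confounded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

from .exceptions import DegenerateDataError
from .simulate import stable_seed

__all__ = [
    "CoexStat",
    "ConservationCall",
    "median_pairwise_r2",
    "diff_coexpression_test",
    "conservation_test",
    "eigengene",
    "phenotype_association",
]


@dataclass(frozen=True)
class CoexStat:
    module_id: str
    median_r2_disease: float
    median_r2_control: float
    delta_r2: float
    p_empirical: float
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        assert abs(self.delta_r2 - (self.median_r2_disease - self.median_r2_control)) < 1e-12
        assert self.p_empirical >= 1.0 / (self.n_perm + 1) - 1e-15


@dataclass(frozen=True)
class ConservationCall:
    module_id: str
    target_cohort: str
    median_r2_target: float
    p_empirical: float
    conserved: bool
    n_perm: int
    alpha: float = 0.05


def _pair_r2(arr: np.ndarray, method: str = "spearman") -> np.ndarray:
    """Squared correlations over unordered gene pairs of a genes x samples array."""
    if method == "spearman":
        x = rankdata(arr, axis=1)
    elif method == "pearson":
        x = np.asarray(arr, dtype=float)
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    x = x - x.mean(axis=1, keepdims=True)
    sd = np.sqrt((x**2).sum(axis=1))
    if (sd == 0).any():
        raise DegenerateDataError("constant gene in correlation computation")
    x /= sd[:, None]
    rho = np.clip(x @ x.T, -1.0, 1.0)
    iu = np.triu_indices(rho.shape[0], k=1)
    return rho[iu] ** 2


def median_pairwise_r2(expr: pd.DataFrame | np.ndarray, method: str = "spearman") -> float:
    """Median of squared pairwise correlations among the rows (genes)."""
    arr = expr.to_numpy() if isinstance(expr, pd.DataFrame) else np.asarray(expr, float)
    if arr.shape[0] < 2:
        raise DegenerateDataError("need >= 2 genes")
    if arr.shape[1] < 4:
        raise DegenerateDataError("need >= 4 samples")
    return float(np.median(_pair_r2(arr, method=method)))


def diff_coexpression_test(
    module_genes,
    expr_disease: pd.DataFrame,
    expr_control: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
    module_id: str = "",
    method: str = "spearman",
) -> CoexStat:
    """Two-sided permutation test on delta = median R^2(disease) - median R^2(control).

    The null permutes the disease/control labels over the pooled samples,
    preserving arm sizes.  p = (1 + #{|delta*| >= |delta_obs|}) / (n_perm + 1).
    The permutation stream is seeded per module so results are independent
    of execution order.
    """
    genes = list(module_genes.genes) if hasattr(module_genes, "genes") else list(module_genes)
    mid = module_id or (module_genes.module_id if hasattr(module_genes, "module_id") else "")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low for an empirical p-value", stacklevel=2)
    # canonical sample order: empirical p invariant to input column order
    d = expr_disease.loc[genes, sorted(expr_disease.columns)].to_numpy(dtype=float)
    c = expr_control.loc[genes, sorted(expr_control.columns)].to_numpy(dtype=float)
    n_d, n_c = d.shape[1], c.shape[1]
    if n_d < 4 or n_c < 4:
        raise DegenerateDataError("both arms need >= 4 samples")
    r2_d = float(np.median(_pair_r2(d, method)))
    r2_c = float(np.median(_pair_r2(c, method)))
    delta_obs = r2_d - r2_c

    pooled = np.concatenate([d, c], axis=1)
    n_tot = n_d + n_c
    eff_seed = stable_seed(seed, mid) if mid else int(seed) % (2**31)
    rng = np.random.default_rng(eff_seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_tot)
        pd_ = pooled[:, perm[:n_d]]
        pc_ = pooled[:, perm[n_d:]]
        delta = np.median(_pair_r2(pd_, method)) - np.median(_pair_r2(pc_, method))
        if abs(delta) >= abs(delta_obs) - 1e-15:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return CoexStat(
        module_id=mid,
        median_r2_disease=r2_d,
        median_r2_control=r2_c,
        delta_r2=delta_obs,
        p_empirical=p,
        n_perm=n_perm,
        seed=eff_seed,
    )


def conservation_test(
    module_genes,
    target_expr: pd.DataFrame,
    target_cohort: str = "",
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    module_id: str = "",
    method: str = "spearman",
    min_mappable: float = 0.5,
) -> ConservationCall:
    """Is a module's coexpression present in another cohort?

    The observed statistic is the median pairwise R^2 of the module's
    mappable genes in the target matrix; the null redraws random gene sets
    of the same size from the target cohort's expressed genes.  One-sided
    empirical p for exceeding the null; conserved iff p < alpha.
    """
    genes = list(module_genes.genes) if hasattr(module_genes, "genes") else list(module_genes)
    mid = module_id or (module_genes.module_id if hasattr(module_genes, "module_id") else "")
    present = [g for g in genes if g in target_expr.index]
    if len(present) < max(2, min_mappable * len(genes)):
        raise DegenerateDataError(
            f"module {mid or '?'}: only {len(present)}/{len(genes)} genes mappable "
            f"in target cohort (need >= {min_mappable:.0%})"
        )
    arr = target_expr.loc[present].to_numpy(dtype=float)
    obs = float(np.median(_pair_r2(arr, method)))
    all_genes = np.asarray(target_expr.index)
    full = target_expr.to_numpy(dtype=float)
    eff_seed = stable_seed(seed, f"cons:{mid}:{target_cohort}") if mid else int(seed) % (2**31)
    rng = np.random.default_rng(eff_seed)
    m = len(present)
    count = 0
    for _ in range(n_perm):
        idx = rng.choice(all_genes.size, size=m, replace=False)
        stat = np.median(_pair_r2(full[idx], method))
        if stat >= obs - 1e-15:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return ConservationCall(
        module_id=mid,
        target_cohort=target_cohort,
        median_r2_target=obs,
        p_empirical=p,
        conserved=bool(p < alpha),
        n_perm=n_perm,
        alpha=alpha,
    )


def eigengene(expr: pd.DataFrame) -> pd.Series:
    """Module eigengene: first-PC sample scores of the gene-standardized
    submatrix, sign-fixed to correlate non-negatively with the mean member
    profile, unit variance."""
    if expr.shape[0] < 2:
        raise DegenerateDataError("eigengene needs >= 2 genes")
    arr = expr.to_numpy(dtype=float)
    z = arr - arr.mean(axis=1, keepdims=True)
    sd = z.std(axis=1)
    if (sd == 0).all():
        raise DegenerateDataError("constant submatrix")
    sd[sd == 0] = 1.0
    z /= sd[:, None]
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    scores = vt[0]
    if np.dot(scores, z.mean(axis=0)) < 0:
        scores = -scores
    s = scores.std()
    return pd.Series(scores / (s if s > 0 else 1.0), index=expr.columns, name="eigengene")


def phenotype_association(
    eig: pd.Series,
    covariate: pd.Series,
    extra_covariates: pd.DataFrame | None = None,
    sample_meta: pd.DataFrame | None = None,
) -> tuple[float, float, float]:
    """OLS of the eigengene on a phenotype covariate; returns (slope, t, p).

    When the covariate is epilepsy duration, patient age is automatically
    added to the design (duration is confounded with age); it is pulled from
    ``extra_covariates`` or ``sample_meta``.
    """
    samples = [s for s in eig.index if s in covariate.index]
    y = eig.loc[samples].to_numpy(dtype=float)
    x = pd.DataFrame({str(covariate.name or "covariate"): covariate.loc[samples]})
    if extra_covariates is not None:
        for col in extra_covariates.columns:
            x[col] = extra_covariates.loc[samples, col].to_numpy(dtype=float)
    if str(covariate.name).lower() == "duration" and "age" not in x.columns:
        if sample_meta is not None and "age" in sample_meta.columns:
            x["age"] = sample_meta.loc[samples, "age"].to_numpy(dtype=float)
        else:
            raise DegenerateDataError(
                "duration requires age as an additional covariate; provide it"
            )
    if len(samples) < 5 + x.shape[1]:
        raise DegenerateDataError("too few samples for the requested design")
    design = sm.add_constant(x.to_numpy(dtype=float))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DegenerateDataError("collinear design matrix")
    fit = sm.OLS(y, design).fit()
    return float(fit.params[1]), float(fit.tvalues[1]), float(fit.pvalues[1])
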