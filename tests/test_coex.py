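"""Differential coexpression, conservation, eigengene and phenotype tests."""

import numpy as np
import pandas as pd
import pytest

from epiregulome import (
    conservation_test,
    diff_coexpression_test,
    eigengene,
    median_pairwise_r2,
    phenotype_association,
)
from epiregulome.exceptions import DegenerateDataError


def _expr(rows, prefix="s"):
    rows = np.asarray(rows, dtype=float)
    return pd.DataFrame(rows, index=[f"g{i}" for i in range(rows.shape[0])],
                        columns=[f"{prefix}{j}" for j in range(rows.shape[1])])


class TestMedianPairwiseR2:
    def test_identical_genes(self):
        assert median_pairwise_r2(_expr([[1, 2, 3, 4], [1, 2, 3, 4]])) == pytest.approx(1.0)

    def test_antimonotone_pairs_square_to_one(self):
        expr = _expr([[1, 2, 3, 4], [4, 3, 2, 1]])
        assert median_pairwise_r2(expr) == pytest.approx(1.0)

    def test_rank_design_triple(self):
        """Three genes with pairwise Spearman rho = (0.9, 0.5, 0.1) by exact
        rank design -> squared (0.81, 0.25, 0.01), median 0.25."""
        a = [1, 2, 3, 4, 5]
        b = [1, 2, 4, 3, 5]
        c = [3, 2, 1, 5, 4]
        assert median_pairwise_r2(_expr([a, b, c])) == pytest.approx(0.25)

    def test_constant_gene_rejected(self):
        with pytest.raises(DegenerateDataError):
            median_pairwise_r2(_expr([[1, 1, 1, 1], [1, 2, 3, 4]]))

    def test_bounds(self):
        rng = np.random.default_rng(0)
        v = median_pairwise_r2(_expr(rng.normal(size=(6, 20))))
        assert 0.0 <= v <= 1.0


class TestDiffCoexpression:
    def _arms(self, seed=0, n=12, m=6, coexpressed=True):
        rng = np.random.default_rng(seed)
        if coexpressed:
            f = rng.normal(size=n)
            d = np.vstack([f + rng.normal(0, 0.3, n) for _ in range(m)])
        else:
            d = rng.normal(size=(m, n))
        c = rng.normal(size=(m, n))
        return _expr(d, "d"), _expr(c, "c")

    def test_extreme_delta_attains_floor(self):
        d, c = self._arms(coexpressed=True)
        stat = diff_coexpression_test(list(d.index), d, c, n_perm=200, seed=1,
                                      module_id="m")
        assert stat.p_empirical == pytest.approx(1 / 201)
        assert stat.delta_r2 == pytest.approx(
            stat.median_r2_disease - stat.median_r2_control
        )

    def test_deterministic_under_seed_and_label_order(self):
        d, c = self._arms(seed=3, coexpressed=False)
        s1 = diff_coexpression_test(list(d.index), d, c, n_perm=200, seed=5,
                                    module_id="m")
        s2 = diff_coexpression_test(list(d.index), d, c, n_perm=200, seed=5,
                                    module_id="m")
        s3 = diff_coexpression_test(
            list(d.index), d[d.columns[::-1]], c[c.columns[::-1]], n_perm=200,
            seed=5, module_id="m",
        )
        assert s1.p_empirical == s2.p_empirical == s3.p_empirical

    def test_p_never_zero(self):
        d, c = self._arms(coexpressed=True)
        stat = diff_coexpression_test(list(d.index), d, c, n_perm=150, seed=2,
                                      module_id="m")
        assert stat.p_empirical >= 1 / 151

    def test_low_n_perm_warns(self):
        d, c = self._arms()
        with pytest.warns(UserWarning, match="n_perm"):
            diff_coexpression_test(list(d.index), d, c, n_perm=50, seed=0,
                                   module_id="m")

    def test_degenerate_arm_rejected(self):
        d, c = self._arms()
        with pytest.raises(DegenerateDataError):
            diff_coexpression_test(list(d.index), d.iloc[:, :3], c, n_perm=100,
                                   seed=0, module_id="m")

    def test_delta_estimator_consistency(self, disease_control):
        """Planted Delta is recovered by the observed statistic."""
        expr_d, expr_c, truth = disease_control
        genes = list(truth.module_genes["M1"])
        stat = diff_coexpression_test(genes, expr_d, expr_c, n_perm=100, seed=0,
                                      module_id="A.M1")
        planted = truth.module_targets["M1"][0] - truth.module_targets["M1"][1]
        assert abs(stat.delta_r2 - planted) <= 0.15
        assert stat.p_empirical < 0.05


class TestConservation:
    def test_planted_module_conserved(self, disease_control):
        expr_d, _, truth = disease_control
        genes = list(truth.module_genes["M1"])
        call = conservation_test(genes, expr_d, "A", n_perm=200, seed=0,
                                 module_id="A.M1")
        assert call.conserved and call.p_empirical < 0.05

    def test_random_set_rarely_conserved(self, disease_control):
        expr_d, _, truth = disease_control
        rng = np.random.default_rng(11)
        background = [g for g in expr_d.index if g.startswith("bg")]
        hits = 0
        for rep in range(20):
            genes = list(rng.choice(background, size=15, replace=False))
            call = conservation_test(genes, expr_d, "A", n_perm=99, seed=rep,
                                     module_id=f"rand{rep}")
            hits += call.conserved
        assert hits <= 4  # ~alpha-level

    def test_unmappable_module_rejected(self, disease_control):
        expr_d, _, truth = disease_control
        genes = list(truth.module_genes["M1"])[:6] + [f"missing{i}" for i in range(10)]
        with pytest.raises(DegenerateDataError, match="mappable"):
            conservation_test(genes, expr_d, "A", n_perm=50, seed=0, module_id="m")


class TestEigengene:
    def test_identical_genes_returns_profile(self):
        base = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        expr = _expr([base, base])
        eig = eigengene(expr)
        z = (base - base.mean()) / base.std()
        assert np.allclose(eig.to_numpy(), z)
        assert np.corrcoef(eig, base)[0, 1] > 0.999

    def test_sign_convention_positive_vs_mean(self):
        rng = np.random.default_rng(1)
        f = rng.normal(size=20)
        expr = _expr([f + rng.normal(0, 0.2, 20) for _ in range(5)])
        eig = eigengene(expr)
        assert np.corrcoef(eig, expr.mean(axis=0))[0, 1] > 0

    def test_balanced_anticorrelated_halves(self):
        rng = np.random.default_rng(2)
        f = rng.normal(size=40)
        up = [f + rng.normal(0, 0.05, 40) for _ in range(6)]
        dn = [-f + rng.normal(0, 0.05, 40) for _ in range(6)]
        expr = _expr(up + dn)
        eig = eigengene(expr)
        c_up = abs(np.corrcoef(eig, expr.iloc[:6].mean(axis=0))[0, 1])
        c_dn = abs(np.corrcoef(eig, expr.iloc[6:].mean(axis=0))[0, 1])
        assert abs(c_up - c_dn) <= 0.05

    def test_unit_variance(self):
        rng = np.random.default_rng(3)
        eig = eigengene(_expr(rng.normal(size=(6, 15))))
        assert eig.to_numpy().std() == pytest.approx(1.0)

    def test_constant_submatrix_rejected(self):
        with pytest.raises(DegenerateDataError):
            eigengene(_expr([[1, 1, 1, 1], [2, 2, 2, 2]]))


class TestPhenotypeAssociation:
    def test_covariate_equal_to_eigengene(self):
        rng = np.random.default_rng(4)
        eig = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
        cov = eig.copy()
        cov.name = "score"
        slope, t, p = phenotype_association(eig, cov)
        assert slope == pytest.approx(1.0)
        assert p < 1e-12

    def test_null_calibration(self):
        """Independent covariate: rejection rate near alpha."""
        rng = np.random.default_rng(5)
        idx = [f"s{i}" for i in range(50)]
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            eig = pd.Series(rng.normal(size=50), index=idx)
            cov = pd.Series(rng.normal(size=50), index=idx, name="x")
            _, _, p = phenotype_association(eig, cov)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_duration_adds_age_covariate(self):
        rng = np.random.default_rng(6)
        idx = [f"s{i}" for i in range(40)]
        eig = pd.Series(rng.normal(size=40), index=idx)
        age = pd.Series(rng.uniform(10, 60, 40), index=idx)
        duration = pd.Series(0.5 * age + rng.normal(0, 2, 40), index=idx,
                             name="duration")
        meta = pd.DataFrame({"age": age})
        slope_adj, _, _ = phenotype_association(eig, duration, sample_meta=meta)
        # without metadata carrying age, duration analyses must refuse
        with pytest.raises(DegenerateDataError, match="age"):
            phenotype_association(eig, duration)
        # and the adjusted slope differs from a naive fit with age supplied
        naive = duration.copy()
        naive.name = "dur_raw"
        slope_naive, _, _ = phenotype_association(eig, naive)
        assert np.isfinite(slope_adj) and np.isfinite(slope_naive)

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(7)
        idx = [f"s{i}" for i in range(30)]
        eig = pd.Series(rng.normal(size=30), index=idx)
        cov = pd.Series(rng.normal(size=30), index=idx, name="x")
        extra = pd.DataFrame({"x2": 2 * cov}, index=idx)
        with pytest.raises(DegenerateDataError, match="collinear"):
            phenotype_association(eig, cov, extra_covariates=extra)
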