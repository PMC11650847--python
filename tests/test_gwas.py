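import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

from seldrift import (
    GenotypeMatrix,
    bonferroni_threshold,
    build_design,
    compute_grm,
    genomic_inflation,
    reml_null,
    simulate_gwas_cohort,
    snp_scan,
    variance_explained,
)
from seldrift.gwas import CHI2_1_MEDIAN, GwasResult, build_covariance


def make_matrix(dosages, animal_ids=None):
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    return GenotypeMatrix(
        animal_ids or [f"A{k:04d}" for k in range(n)],
        [f"M{k:04d}" for k in range(m)],
        np.array(["1"] * m, dtype=object),
        np.arange(1, m + 1),
        d,
    )


def gls_oracle(y, X, V, w):
    """From-scratch per-SNP GLS with explicit V: weighted normal equations."""
    C = np.column_stack([X, w])
    Vi = np.linalg.inv(V)
    M = C.T @ Vi @ C
    beta = np.linalg.solve(M, C.T @ Vi @ y)
    cov = np.linalg.inv(M)
    eff, se = beta[-1], np.sqrt(cov[-1, -1])
    z = eff / se
    return eff, se, 2 * stats.norm.sf(abs(z))


class TestGrm:
    def test_hand_computed_two_by_two(self):
        g = make_matrix([[0, 2], [2, 0]])
        grm = compute_grm(g)
        assert grm.denominator == pytest.approx(1.0)
        assert np.allclose(grm.matrix, [[2, -2], [-2, 2]])

    def test_grand_sum_zero_with_data_frequencies(self):
        rng = np.random.default_rng(0)
        g = make_matrix(rng.integers(0, 3, size=(40, 100)))
        grm = compute_grm(g)
        assert abs(grm.matrix.sum()) < 1e-10 * np.abs(grm.matrix).max() * grm.matrix.size

    def test_marker_duplication_invariance(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(20, 30)).astype(float)
        g1 = compute_grm(make_matrix(d)).matrix
        g2 = compute_grm(make_matrix(np.hstack([d, d]))).matrix
        assert np.allclose(g1, g2)

    def test_monomorphic_marker_rejected(self):
        g = make_matrix([[2, 1], [2, 0]])
        with pytest.raises(ValueError, match="M0000"):
            compute_grm(g)

    def test_missing_dosages_rejected(self):
        g = make_matrix([[np.nan, 1], [2, 0]])
        with pytest.raises(ValueError, match="complete"):
            compute_grm(g)


class TestRemlNull:
    def test_h2_recovery_marker_grm(self):
        rng = np.random.default_rng(10)
        cohort = simulate_gwas_cohort(1200, 800, rng, h2_polygenic=0.5)
        grm = compute_grm(cohort.genotypes)
        design = build_design(cohort.phenotypes, "y", cohort.genotypes.animal_ids)
        vc = reml_null(design, grm)
        assert vc.h2 == pytest.approx(0.5, abs=0.07)
        assert vc.converged

    def test_zero_variance_response_errors(self):
        g = make_matrix(np.random.default_rng(0).integers(0, 3, size=(30, 50)))
        pheno = pd.DataFrame({"animal_id": g.animal_ids, "y": 1.0})
        design = build_design(pheno, "y", g.animal_ids)
        with pytest.raises(ValueError, match="zero variance"):
            reml_null(design, compute_grm(g))

    def test_profile_likelihood_peaks_near_truth(self):
        # restricted likelihood at the REML optimum exceeds the likelihood
        # at a doubled genetic variance
        rng = np.random.default_rng(3)
        cohort = simulate_gwas_cohort(800, 600, rng, h2_polygenic=0.35)
        grm = compute_grm(cohort.genotypes)
        design = build_design(cohort.phenotypes, "y", cohort.genotypes.animal_ids)
        vc = reml_null(design, grm)
        from seldrift.gwas import _reml_loglik

        V_hat = build_covariance(design, grm, vc)
        ll_hat = _reml_loglik(design.y, design.X, V_hat)
        vc2 = type(vc)(2.5 * vc.sigma2_a, vc.sigma2_e)
        ll_2x = _reml_loglik(design.y, design.X, build_covariance(design, grm, vc2))
        assert ll_hat >= ll_2x

    def test_extra_random_factor_recovery(self):
        # y = mu + batch + g + e with known variances; the general REML path
        # must attribute variance to the right components
        rng = np.random.default_rng(8)
        n = 600
        cohort = simulate_gwas_cohort(n, 500, rng, h2_polygenic=0.4, var_p=1.0)
        batches = rng.integers(0, 30, size=n)
        b_eff = rng.normal(0, np.sqrt(0.3), size=30)
        pheno = cohort.phenotypes.copy()
        pheno["batch"] = [f"b{b}" for b in batches]
        pheno["y"] = pheno["y"] + b_eff[batches]
        design = build_design(pheno, "y", cohort.genotypes.animal_ids, random=["batch"])
        vc = reml_null(design, compute_grm(cohort.genotypes))
        assert vc.extra["batch"] == pytest.approx(0.3, abs=0.15)
        assert vc.sigma2_a == pytest.approx(0.4, abs=0.15)


class TestSnpScan:
    @staticmethod
    def _small_instance(seed=0, n=120, m=12, with_batch=True):
        rng = np.random.default_rng(seed)
        cohort = simulate_gwas_cohort(n, m, rng, h2_polygenic=0.3,
                                      qtl_variance_frac=0.05)
        pheno = cohort.phenotypes.copy()
        pheno["sex"] = np.where(rng.random(n) < 0.5, "m", "f")
        if with_batch:
            pheno["batch"] = [f"b{k}" for k in rng.integers(0, 5, size=n)]
        design = build_design(
            pheno, "y", cohort.genotypes.animal_ids, fixed=["sex"],
            random=["batch"] if with_batch else [],
        )
        grm = compute_grm(cohort.genotypes)
        return cohort, design, grm

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_bruteforce_gls_oracle(self, seed):
        cohort, design, grm = self._small_instance(seed)
        vc = reml_null(design, grm, max_iter=200)
        res = snp_scan(design, grm, vc, cohort.genotypes)
        V = build_covariance(design, grm, vc)
        W = design.Z2 @ cohort.genotypes.dosages
        for j in range(cohort.genotypes.n_markers):
            eff, se, p = gls_oracle(design.y, design.X, V, W[:, j])
            assert res.frame["effect"].iloc[j] == pytest.approx(eff, rel=1e-8)
            assert res.frame["se"].iloc[j] == pytest.approx(se, rel=1e-8)
            assert res.frame["p"].iloc[j] == pytest.approx(p, rel=1e-6, abs=1e-12)

    def test_degenerates_to_ols_without_random_effects(self):
        cohort, design, grm = self._small_instance(3, with_batch=False)
        from seldrift.gwas import VarianceComponents

        vc = VarianceComponents(sigma2_a=0.0, sigma2_e=1.0)
        res = snp_scan(design, grm, vc, cohort.genotypes)
        w = (design.Z2 @ cohort.genotypes.dosages)[:, 0]
        Xw = np.column_stack([design.X, w])
        beta = np.linalg.lstsq(Xw, design.y, rcond=None)[0]
        assert res.frame["effect"].iloc[0] == pytest.approx(beta[-1], rel=1e-9)

    def test_permutation_invariance(self):
        cohort, design, grm = self._small_instance(4, n=80, m=8)
        rng = np.random.default_rng(0)
        perm = rng.permutation(cohort.genotypes.n_animals)
        ids_p = [cohort.genotypes.animal_ids[k] for k in perm]
        g_p = cohort.genotypes.subset(animals=ids_p)
        pheno_p = cohort.phenotypes.set_index("animal_id").loc[ids_p].reset_index()
        design_p = build_design(pheno_p, "y", g_p.animal_ids)
        design_0 = build_design(cohort.phenotypes, "y", cohort.genotypes.animal_ids)
        grm_p = compute_grm(g_p)
        vc0 = reml_null(design_0, grm)
        res0 = snp_scan(design_0, grm, vc0, cohort.genotypes)
        vcp = reml_null(design_p, grm_p)
        resp = snp_scan(design_p, grm_p, vcp, g_p)
        assert np.allclose(res0.frame["effect"], resp.frame["effect"], rtol=1e-6)
        assert np.allclose(res0.frame["p"], resp.frame["p"], rtol=1e-5, atol=1e-12)

    def test_monomorphic_marker_not_estimable(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, size=(60, 6)).astype(float)
        d[:, 2] = 1.0  # constant dosage, collinear with the mean
        g = make_matrix(d)
        poly = g.subset(markers=[m for k, m in enumerate(g.marker_ids) if k != 2])
        grm = compute_grm(poly)
        pheno = pd.DataFrame({"animal_id": g.animal_ids, "y": rng.normal(size=60)})
        design = build_design(pheno, "y", g.animal_ids)
        vc = reml_null(design, grm)
        res = snp_scan(design, grm, vc, g)
        assert np.isnan(res.frame["effect"].iloc[2])
        assert res.n_estimable == 5

    def test_null_pvalues_uniform_single_run(self):
        rng = np.random.default_rng(12)
        cohort = simulate_gwas_cohort(500, 200, rng, h2_polygenic=0.3, n_background=800)
        grm = compute_grm(cohort.background)
        design = build_design(cohort.phenotypes, "y", cohort.genotypes.animal_ids)
        vc = reml_null(design, grm)
        res = snp_scan(design, grm, vc, cohort.genotypes)
        ks = stats.kstest(res.frame["p"].dropna(), "uniform")
        assert ks.pvalue > 0.01


class TestThresholdAndVariance:
    def test_bonferroni_values(self):
        assert bonferroni_threshold(0.05, 44056) == pytest.approx(5.9450, abs=5e-4)
        assert bonferroni_threshold(0.05, 1) == pytest.approx(1.30103, abs=1e-5)
        assert bonferroni_threshold(1.0, 1) == 0.0
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)

    def test_variance_explained(self):
        assert variance_explained(0.5, 1.0) == pytest.approx(0.5)
        assert variance_explained(0.0, 123.0) == 0.0
        assert variance_explained(0.2, 2.0) == pytest.approx(1.28)
        assert variance_explained(0.2, 2.0, phenotypic_variance=2.0) == pytest.approx(0.64)
        with pytest.raises(ValueError):
            variance_explained(1.5, 1.0)


class TestGenomicInflation:
    @staticmethod
    def _result_from_z(z):
        p = 2 * stats.norm.sf(np.abs(z))
        frame = pd.DataFrame(
            {"marker": [f"M{k}" for k in range(len(z))], "chrom": "1",
             "pos": np.arange(len(z)), "maf": 0.3, "effect": z, "se": 1.0,
             "z": z, "p": p, "neglog10p": -np.log10(p), "var_explained": 0.0}
        )
        return GwasResult(frame, "y", len(z))

    def test_lambda_one_under_null(self):
        z = np.random.default_rng(0).normal(size=100_000)
        lam, _ = genomic_inflation(self._result_from_z(z))
        assert lam == pytest.approx(1.0, abs=0.02)

    def test_lambda_linear_in_statistic(self):
        z = np.random.default_rng(1).normal(size=20_000)
        lam1, _ = genomic_inflation(self._result_from_z(z))
        lam2, _ = genomic_inflation(self._result_from_z(np.sqrt(2) * z))
        assert lam2 == pytest.approx(2 * lam1, rel=1e-9)

    def test_qq_plotting_positions(self):
        z = np.array([0.5, 1.0, 1.5] * 4)
        lam, qq = genomic_inflation(self._result_from_z(z))
        n = len(z)
        assert np.allclose(
            qq["expected_neglog10p"], -np.log10(np.arange(1, n + 1) / (n + 1))
        )
        assert (np.diff(qq["observed_neglog10p"]) <= 1e-12).all()

    def test_chi2_median_constant(self):
        assert stats.chi2.ppf(0.5, 1) == pytest.approx(CHI2_1_MEDIAN, abs=1e-6)
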