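"""Kinship, PCs, BIC selection, GWAS/TWAS scan tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from waxomics import assoc, synthdata as sd, traitprep as tp
from waxomics.synthdata import GenotypeMatrix


def _gm_from_dosages(dos, chrom="1"):
    dos = np.asarray(dos)
    n, m = dos.shape
    meta = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chrom": [chrom] * m,
            "pos": np.arange(1, m + 1) * 1000,
            "maf": np.minimum(dos.mean(axis=0) / 2, 1 - dos.mean(axis=0) / 2),
            "dr2": np.ones(m),
        }
    )
    return GenotypeMatrix(dosages=dos, snp_meta=meta, line_ids=[f"L{i}" for i in range(n)])


class TestKinship:
    def test_hand_worked_three_by_four(self):
        dos = np.array([[0, 2, 2, 0], [2, 0, 2, 0], [0, 2, 0, 2]], dtype=float)
        p = dos.mean(axis=0) / 2
        W = dos - 2 * p
        expected = W @ W.T / (2 * np.sum(p * (1 - p)))
        K = assoc.compute_kinship(_gm_from_dosages(dos))
        np.testing.assert_allclose(K.values, expected, atol=1e-12)

    def test_identical_lines_share_diagonal_value(self):
        rng = np.random.default_rng(0)
        dos = rng.choice([0, 2], size=(6, 50))
        dos[1] = dos[0]
        K = assoc.compute_kinship(_gm_from_dosages(dos)).values
        assert K[0, 1] == pytest.approx(K[0, 0], rel=1e-12)
        assert K[0, 1] == pytest.approx(K[1, 1], rel=1e-12)

    def test_symmetric_psd_inbred_diagonal(self, small_population):
        K = assoc.compute_kinship(small_population).values
        assert np.abs(K - K.T).max() < 1e-10
        assert np.linalg.eigvalsh(K).min() >= -1e-8
        # fully inbred panel: mean diagonal ~ 1 + f = 2
        assert np.diag(K).mean() == pytest.approx(2.0, abs=0.05)

    def test_monomorphic_snps_excluded_with_warning(self):
        rng = np.random.default_rng(1)
        dos = rng.choice([0, 2], size=(10, 20))
        dos[:, 3] = 2
        with pytest.warns(UserWarning):
            K = assoc.compute_kinship(_gm_from_dosages(dos))
        assert np.isfinite(K.values).all()


class TestPCs:
    def test_orthogonal_scores_with_decreasing_variance(self, small_population):
        S = assoc.compute_pcs(small_population, 4)
        G = S.T @ S
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-6
        v = S.var(axis=0)
        assert all(a >= b - 1e-9 for a, b in zip(v, v[1:]))

    def test_k_zero_returns_empty(self, small_population):
        assert assoc.compute_pcs(small_population, 0).shape == (150, 0)

    def test_recovers_subpopulations(self):
        gm = sd.simulate_population(n_lines=210, n_snps=800, n_subpops=3, fst=0.15, seed=17)
        S = assoc.compute_pcs(gm, 2)
        labels = KMeans(n_clusters=3, n_init=10, random_state=0).fit_predict(S)
        assert adjusted_rand_score(gm.subpop, labels) > 0.8


class TestModelSelection:
    def test_bic_formula(self):
        assert assoc.bic(-100.0, 3, 300) == pytest.approx(200 + 3 * np.log(300))

    def test_covariate_effect_detected(self, small_population):
        K = assoc.compute_kinship(small_population)
        rng = np.random.default_rng(3)
        covar = rng.standard_normal(150)
        y = 1.5 * covar + rng.standard_normal(150)
        spec = assoc.select_model_bic(
            y, {"kinship_only": None, "flowering": covar}, K
        )
        assert spec.covariates == ["flowering"]

    def test_kinship_only_selected_under_pure_polygenic_trait(self, small_population):
        K = assoc.compute_kinship(small_population)
        L = np.linalg.cholesky(K.values + 1e-8 * np.eye(150))
        wins = 0
        reps = 10
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            y = L @ rng.standard_normal(150) + 0.5 * rng.standard_normal(150)
            covar = rng.standard_normal(150)  # irrelevant candidate
            spec = assoc.select_model_bic(y, {"kinship_only": None, "flowering": covar}, K)
            wins += spec.covariates == []
        assert wins >= 9

    def test_tie_goes_to_smaller_model(self, small_population):
        K = assoc.compute_kinship(small_population)
        rng = np.random.default_rng(5)
        y = rng.standard_normal(150)
        zero_cov = np.zeros(150)  # adds a parameter, no fit improvement
        spec = assoc.select_model_bic(y, {"kinship_only": None, "null_cov": zero_cov}, K)
        assert spec.covariates == []


class TestGwasScan:
    def test_identity_kinship_matches_ols(self, small_population):
        rng = np.random.default_rng(7)
        y = rng.standard_normal(150)
        Kid = assoc.KinshipMatrix(np.eye(150), small_population.line_ids)
        tab = assoc.gwas_scan(y, small_population, Kid, mode="p3d")
        X = small_population.dosages.astype(float)
        for j in range(0, 400, 23):
            p_ols = stats.linregress(X[:, j], y).pvalue
            assert abs(p_ols - tab["p"].iloc[j]) < 1e-6

    def test_constant_snp_reports_p_one(self):
        rng = np.random.default_rng(8)
        dos = rng.choice([0, 2], size=(60, 10))
        dos[:, 4] = 0
        gm = _gm_from_dosages(dos)
        Kid = assoc.KinshipMatrix(np.eye(60), gm.line_ids)
        tab = assoc.gwas_scan(rng.standard_normal(60), gm, Kid)
        assert tab["p"].iloc[4] == 1.0 and tab["effect"].iloc[4] == 0.0

    def test_permuting_lines_leaves_pvalues_unchanged(self, small_population):
        """Consistent line reordering changes no p-value beyond optimizer roundoff.

        The variance-ratio optimum is flat, so its numerically located argmin
        (and hence each p) is reproducible only to ~sqrt(eps); 1e-6 bounds
        that roundoff comfortably while catching any real exchangeability bug.
        """
        rng = np.random.default_rng(9)
        y = rng.standard_normal(150)
        K = assoc.compute_kinship(small_population)
        tab1 = assoc.gwas_scan(y, small_population, K)
        perm = rng.permutation(150)
        gm_p = GenotypeMatrix(
            small_population.dosages[perm],
            small_population.snp_meta,
            [small_population.line_ids[i] for i in perm],
        )
        K_p = assoc.KinshipMatrix(K.values[np.ix_(perm, perm)], gm_p.line_ids)
        tab2 = assoc.gwas_scan(y[perm], gm_p, K_p)
        np.testing.assert_allclose(tab1["p"], tab2["p"], atol=1e-6)

    def test_p3d_vs_exact_agree_under_polygenicity(self):
        gm = sd.simulate_population(n_lines=150, n_snps=500, seed=19)
        K = assoc.compute_kinship(gm)
        rng = np.random.default_rng(19)
        X = gm.dosages.astype(float)
        causal = rng.choice(500, size=30, replace=False)
        y = X[:, causal] @ rng.normal(scale=0.2, size=30) + rng.standard_normal(150)
        t1 = assoc.gwas_scan(y, gm, K, mode="p3d")
        t2 = assoc.gwas_scan(y, gm, K, mode="exact")
        rho = stats.spearmanr(-np.log10(t1["p"]), -np.log10(t2["p"])).statistic
        assert rho >= 0.99

    def test_null_inflation_controlled(self):
        gm = sd.simulate_population(n_lines=200, n_snps=2000, n_subpops=3, fst=0.1, seed=23)
        K = assoc.compute_kinship(gm)
        rng = np.random.default_rng(23)
        L = np.linalg.cholesky(K.values + 1e-8 * np.eye(200))
        y = L @ rng.standard_normal(200) + rng.standard_normal(200)
        tab = assoc.gwas_scan(y, gm, K)
        assert 0.9 <= assoc.genomic_inflation(tab["p"].to_numpy()) <= 1.1


class TestR2Likelihood:
    def test_zero_at_equal_likelihoods(self):
        assert assoc.r2_likelihood(-50.0, -50.0, 100) == 0.0

    def test_monotone_in_full_likelihood(self):
        vals = [assoc.r2_likelihood(-50.0 + d, -50.0, 100) for d in (0.1, 1.0, 5.0, 20.0)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_matches_classical_r2_for_ols(self):
        rng = np.random.default_rng(31)
        n = 80
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        # ML log-likelihoods of the gaussian regression with/without x
        for X_full, X_null in [(np.column_stack([np.ones(n), x]), np.ones((n, 1)))]:
            def ml_ll(Xd):
                b = np.linalg.lstsq(Xd, y, rcond=None)[0]
                rss = np.sum((y - Xd @ b) ** 2)
                return -n / 2 * (np.log(2 * np.pi * rss / n) + 1)
            r2 = assoc.r2_likelihood(ml_ll(X_full), ml_ll(X_null), n)
            classical = stats.pearsonr(x, y).statistic ** 2
            assert r2 == pytest.approx(classical, abs=1e-10)

    def test_rejects_decreasing_likelihood(self):
        with pytest.raises(ValueError):
            assoc.r2_likelihood(-51.0, -50.0, 100)


class TestTwasScan:
    def test_identity_kinship_matches_ols(self):
        rng = np.random.default_rng(37)
        n = 100
        E = pd.DataFrame(rng.standard_normal((n, 30)), index=[f"L{i}" for i in range(n)])
        y = rng.standard_normal(n)
        Kid = assoc.KinshipMatrix(np.eye(n), list(E.index))
        tab = assoc.twas_scan(y, E, Kid, per_gene_reml=True)
        for j in range(30):
            p_ols = stats.linregress(E.iloc[:, j], y).pvalue
            assert abs(p_ols - tab["p"].iloc[j]) < 1e-6

    def test_constant_gene_reports_p_one(self):
        rng = np.random.default_rng(38)
        n = 60
        E = pd.DataFrame(rng.standard_normal((n, 5)))
        E.iloc[:, 2] = 3.0
        Kid = assoc.KinshipMatrix(np.eye(n), list(E.index))
        tab = assoc.twas_scan(rng.standard_normal(n), E, Kid)
        assert tab["p"].iloc[2] == 1.0

    def test_null_pvalues_uniform(self):
        gm = sd.simulate_population(n_lines=150, n_snps=300, seed=41)
        lay = sd.simulate_gene_models(n_genes=150, seed=42)
        ex = sd.simulate_expression(gm, lay, cis_h2=0.3, seed=43)
        resid = tp.residualize_expression(ex.line_means(), k_factors=5, screen_outliers=False)
        K = assoc.compute_kinship(gm)
        y = np.random.default_rng(44).standard_normal(150)
        tab = assoc.twas_scan(y, resid, K, per_gene_reml=True)
        assert stats.kstest(tab["p"], "uniform").pvalue > 0.01

    def test_driving_gene_is_top_hit(self):
        gm = sd.simulate_population(n_lines=200, n_snps=400, seed=45)
        lay = sd.simulate_gene_models(n_genes=120, seed=46)
        ex = sd.simulate_expression(gm, lay, cis_h2=0.4, seed=47)
        rng = np.random.default_rng(48)
        e = ex.line_means().iloc[:, 60].to_numpy()
        es = (e - e.mean()) / e.std()
        y = np.sqrt(0.3) * es + np.sqrt(0.7) * rng.standard_normal(200)
        resid = tp.residualize_expression(ex.line_means(), k_factors=5, screen_outliers=False)
        K = assoc.compute_kinship(gm)
        tab = assoc.twas_scan(y, resid, K)
        assert tab.sort_values("p")["feature_id"].iloc[0] == ex.gene_ids[60]


class TestSnpFilters:
    def test_maf_and_dr2_filters(self):
        rng = np.random.default_rng(51)
        dos = rng.choice([0, 2], size=(100, 20), p=[0.5, 0.5])
        dos[:, 0] = np.where(rng.random(100) < 0.02, 2, 0)  # rare
        gm = _gm_from_dosages(dos)
        gm.snp_meta.loc[5, "dr2"] = 0.5
        out = assoc.filter_snps(gm, maf_min=0.05, dr2_min=0.8)
        kept = set(out.snp_meta["snp_id"])
        assert "s0" not in kept and "s5" not in kept
        assert out.n_snps == 18
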