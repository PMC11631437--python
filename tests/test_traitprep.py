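"""Trait QC, REML/BLUP, outlier screening, Box-Cox and residualization tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from waxomics import synthdata as sd, traitprep as tp
from waxomics.mixedmodel import blups_at_components, fit_variance_components


def _plot_table(values_by_line, trait="t1", env=1):
    """Single-trait plot table from {line: [plot values]}."""
    rows = []
    for line, vals in values_by_line.items():
        for v in vals:
            rows.append((line, env, 1, 1, 1, 1, trait, v))
    return pd.DataFrame(
        rows,
        columns=[
            "line_id", "env", "block_id", "column_id",
            "instrument_id", "instrument_column_id", "trait_id", "value",
        ],
    )


class TestZeroFilter:
    def _table_with_zero_frac(self, frac, n_lines=310):
        n_zero = int(round(frac * n_lines))
        vals = {f"L{i}": [0.0 if i < n_zero else 1.0 + i] for i in range(n_lines)}
        return _plot_table(vals)

    def test_over_forty_percent_excluded(self):
        pt = self._table_with_zero_frac(0.41)
        pt2 = pd.concat([pt, _plot_table({f"L{i}": [2.0] for i in range(310)}, trait="keep")])
        out, rep = tp.filter_detectable_traits(pt2)
        assert "t1" in rep.traits_dropped and "t1" not in out["trait_id"].unique()

    def test_exactly_forty_percent_retained(self):
        pt = self._table_with_zero_frac(0.40)
        out, rep = tp.filter_detectable_traits(pt)
        assert "t1" in out["trait_id"].unique() and not rep.traits_dropped

    def test_no_zeros_retained(self):
        out, rep = tp.filter_detectable_traits(self._table_with_zero_frac(0.0))
        assert "t1" in out["trait_id"].unique()

    def test_all_traits_removed_raises(self):
        with pytest.raises(ValueError):
            tp.filter_detectable_traits(self._table_with_zero_frac(0.9))

    def test_line_counts_as_zero_only_if_all_plots_zero(self):
        vals = {f"L{i}": [0.0, 1.0] for i in range(10)}  # one positive plot each
        out, rep = tp.filter_detectable_traits(_plot_table(vals))
        assert not rep.traits_dropped


class TestImputation:
    def test_imputed_values_strictly_inside_bounds(self):
        vals = {f"L{i}": [0.0 if i % 2 else 0.5 + i] for i in range(20)}
        pt = _plot_table(vals)
        out, rep = tp.impute_zero_abundances(pt, seed=1)
        imputed = out.loc[pt["value"] == 0, "value"]
        assert ((imputed > 0) & (imputed < 0.5)).all()
        assert rep.imputation_log["t1"]["1"]["upper_bound"] == 0.5

    def test_per_environment_bound(self):
        pt = pd.concat(
            [
                _plot_table({"A": [0.0], "B": [1.0]}, env=1),
                _plot_table({"A": [0.0], "B": [5.0]}, env=2),
            ],
            ignore_index=True,
        )
        out, _ = tp.impute_zero_abundances(pt, seed=0)
        v1 = out[(out["env"] == 1) & (out["line_id"] == "A")]["value"].iloc[0]
        v2 = out[(out["env"] == 2) & (out["line_id"] == "A")]["value"].iloc[0]
        assert 0 < v1 < 1.0 and 0 < v2 < 5.0

    def test_no_zero_table_unchanged_and_deterministic(self):
        pt = _plot_table({f"L{i}": [1.0 + i] for i in range(5)})
        out, _ = tp.impute_zero_abundances(pt, seed=3)
        pd.testing.assert_frame_equal(out, pt)
        pt0 = _plot_table({f"L{i}": [0.0 if i == 0 else 1.0] for i in range(5)})
        a, _ = tp.impute_zero_abundances(pt0, seed=3)
        b, _ = tp.impute_zero_abundances(pt0, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_entirely_zero_cell_raises(self):
        with pytest.raises(ValueError):
            tp.impute_zero_abundances(_plot_table({"A": [0.0], "B": [0.0]}), seed=0)


class TestMixedModel:
    def test_noiseless_limit_blups_are_centered_line_means(self):
        rng = np.random.default_rng(0)
        effects = {f"L{i:02d}": float(rng.normal(scale=2)) for i in range(30)}
        vals = {l: [10 + e, 10 + e] for l, e in effects.items()}  # zero residual
        pt = _plot_table(vals)
        _, blup, _ = tp.fit_trait_mixed_model(pt, "t1", random_terms=("genotype",))
        means = pd.Series({l: np.mean(v) for l, v in vals.items()})
        expected = means - means.mean()
        assert np.abs(blup.sort_index() - expected.sort_index()).max() < 1e-6

    def test_zero_genetic_variance_shrinks_blups(self):
        rng = np.random.default_rng(1)
        vals = {f"L{i:03d}": list(rng.normal(size=4)) for i in range(100)}
        pt = _plot_table(vals)
        vc, blup, _ = tp.fit_trait_mixed_model(pt, "t1", random_terms=("genotype",))
        sd_all = pt["value"].std()
        assert vc["genotype"] < 0.1 * vc["residual"]
        assert blup.abs().max() < 0.1 * sd_all

    def test_reml_estimates_unbiased_one_way(self):
        """Balanced one-way design: REML matches truth on average."""
        rng = np.random.default_rng(2)
        g_hat, e_hat = [], []
        for _ in range(30):
            u = rng.normal(scale=np.sqrt(2.0), size=40)
            y = np.repeat(u, 3) + rng.normal(scale=1.0, size=120)
            vals = {f"L{i:02d}": list(y[3 * i : 3 * i + 3]) for i in range(40)}
            vc, _, _ = tp.fit_trait_mixed_model(_plot_table(vals), "t1", random_terms=("genotype",))
            g_hat.append(vc["genotype"])
            e_hat.append(vc["residual"])
        assert abs(np.mean(g_hat) - 2.0) < 0.25
        assert abs(np.mean(e_hat) - 1.0) < 0.1

    def test_shrinkage_monotone_in_noise_ratio(self):
        rng = np.random.default_rng(3)
        y = np.repeat(rng.normal(size=25), 2) + 0.3 * rng.normal(size=50)
        Z = np.kron(np.eye(25), np.ones((2, 1)))
        X = np.ones((50, 1))
        maxima = [
            np.abs(blups_at_components(y, X, [Z], [1.0], s_e)[0]).max()
            for s_e in (0.1, 1.0, 10.0, 100.0)
        ]
        assert all(a > b for a, b in zip(maxima, maxima[1:]))

    def test_nonconvergence_is_flagged_not_raised(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.ones((4, 1))
        Z = np.eye(4)
        fit = fit_variance_components(y, X, [Z], ["g"], max_iter=1)
        assert fit.vc.converged in (True, False)  # returns, never raises


class TestOutlierScreen:
    def test_displaced_point_is_the_one_removed(self):
        rng = np.random.default_rng(4)
        y = rng.standard_normal(30)
        y[7] += 10.0
        X = np.ones((30, 1))
        kept, removed, _ = tp.screen_outliers_sdr(y, X)
        assert list(removed) == [7]

    def test_matches_brute_force_loo_refit(self):
        rng = np.random.default_rng(5)
        n, p = 25, 3
        X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
        y = X @ rng.standard_normal(p) + rng.standard_normal(n)
        _, _, sdr = tp.screen_outliers_sdr(y, X)
        XtXi = np.linalg.inv(X.T @ X)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        for i in range(n):
            mask = np.arange(n) != i
            b_i = np.linalg.lstsq(X[mask], y[mask], rcond=None)[0]
            mse_i = np.sum((y[mask] - X[mask] @ b_i) ** 2) / (n - 1 - p)
            h_ii = X[i] @ XtXi @ X[i]
            t_i = (y[i] - X[i] @ beta) / np.sqrt(mse_i * (1 - h_ii))
            assert abs(t_i - sdr[i]) < 1e-10

    def test_bonferroni_type1_control(self):
        rng = np.random.default_rng(6)
        removals = 0
        reps = 400
        for _ in range(reps):
            y = rng.standard_normal(30)
            _, removed, _ = tp.screen_outliers_sdr(y, np.ones((30, 1)))
            removals += len(removed) > 0
        rate = removals / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert rate <= 0.05 + 2 * se

    def test_requires_enough_observations(self):
        with pytest.raises(ValueError):
            tp.screen_outliers_sdr(np.ones(3), np.ones((3, 3)))


class TestHeritability:
    def test_arithmetic_example(self):
        vc = tp.VarianceComponents({"genotype": 1.0, "gxe": 1.0, "residual": 1.0}, 0.0, True)
        assert tp.line_mean_heritability(vc, 2, 2) == pytest.approx(1 / 1.75)

    def test_limits(self):
        vc1 = tp.VarianceComponents({"genotype": 1.0, "gxe": 0.0, "residual": 0.0}, 0.0, True)
        assert tp.line_mean_heritability(vc1, 2, 2) == 1.0
        vc0 = tp.VarianceComponents({"genotype": 0.0, "gxe": 1.0, "residual": 1.0}, 0.0, True)
        assert tp.line_mean_heritability(vc0, 2, 2) == 0.0

    def test_all_zero_components_raise(self):
        vc = tp.VarianceComponents({"genotype": 0.0, "gxe": 0.0, "residual": 0.0}, 0.0, True)
        with pytest.raises(ValueError):
            tp.line_mean_heritability(vc, 2, 2)

    def test_harmonic_means_from_design(self):
        pt = pd.concat(
            [
                _plot_table({"A": [1.0], "B": [1.0]}, env=1),
                _plot_table({"A": [1.0]}, env=2),
            ],
            ignore_index=True,
        )
        e_bar, r_bar = tp.design_harmonic_means(pt, "t1")
        assert e_bar == pytest.approx(2 / 1.5)  # harmonic mean of (2, 1)
        assert r_bar == pytest.approx(2 / 1.5)


class TestBoxCox:
    def test_lognormal_snaps_to_zero(self):
        rng = np.random.default_rng(41)
        y = np.exp(rng.standard_normal(300))
        _, lam, _ = tp.boxcox_transform(y)
        assert lam == 0.0

    def test_normal_snaps_to_one(self):
        rng = np.random.default_rng(40)
        y = 5 + rng.standard_normal(300)
        _, lam, _ = tp.boxcox_transform(y)
        assert lam == 1.0

    def test_identity_branch_is_affine(self):
        y = np.linspace(1, 5, 20)
        out, lam, shift = tp.boxcox_transform(y, grid=np.array([1.0]))
        np.testing.assert_allclose(out, y - 1.0)

    def test_nonpositive_values_are_shifted(self):
        rng = np.random.default_rng(43)
        y = rng.standard_normal(100)  # includes negatives
        out, lam, shift = tp.boxcox_transform(y)
        assert shift > 0 and np.isfinite(out).all()


class TestResidualize:
    def test_k_zero_returns_standardized(self):
        rng = np.random.default_rng(44)
        E = pd.DataFrame(rng.standard_normal((50, 10)) * 3 + 5)
        out = tp.residualize_expression(E, k_factors=0, screen_outliers=False)
        np.testing.assert_allclose(out.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_planted_factors_removed(self):
        rng = np.random.default_rng(45)
        n, g, k = 250, 150, 5
        F = rng.standard_normal((n, k))
        W = rng.standard_normal((k, g))
        E = pd.DataFrame(F @ W + 0.3 * rng.standard_normal((n, g)))
        out = tp.residualize_expression(E, k_factors=k, screen_outliers=False)
        s = np.linalg.svd(out.to_numpy(), compute_uv=False)
        assert s[0] ** 2 / np.sum(s**2) < 0.05

    def test_cis_signal_survives_residualization(self):
        chroms = [("1", 10_000_000)]
        gm = sd.simulate_population(n_lines=150, n_snps=300, chrom_lengths=chroms, seed=21)
        lay = sd.simulate_gene_models(n_genes=40, chrom_lengths=chroms, seed=22)
        ex = sd.simulate_expression(gm, lay, cis_window_bp=30_000, cis_h2=0.6, n_latent_factors=5, seed=23)
        raw = ex.line_means()
        resid = tp.residualize_expression(raw, k_factors=5, screen_outliers=False)
        cis = ex.truth.cis_assignments
        X = gm.dosages.astype(float)
        ok = X.std(axis=0) > 0

        def min_p_snp(e):
            pv = np.full(X.shape[1], 1.0)
            for j in np.flatnonzero(ok):
                pv[j] = stats.pearsonr(X[:, j], e).pvalue
            return int(np.argmin(pv))

        kept = 0
        tested = 0
        for gi in cis[cis["has_cis"]].index:
            tested += 1
            if min_p_snp(raw.iloc[:, gi].to_numpy()) == min_p_snp(resid.iloc[:, gi].to_numpy()):
                kept += 1
        assert tested > 5 and kept / tested >= 0.9

    def test_k_too_large_raises(self):
        rng = np.random.default_rng(46)
        E = pd.DataFrame(rng.standard_normal((10, 5)))
        with pytest.raises(ValueError):
            tp.residualize_expression(E, k_factors=5)


class TestPanelPipeline:
    def test_full_pipeline_on_simulated_panel(self):
        gm = sd.simulate_population(n_lines=80, n_snps=150, seed=31)
        cfg = sd.ClassConfig(class_counts={"WE": 3, "PA": 2})
        pt, _, truth = sd.simulate_traits_and_gc(
            gm, None, None, class_config=cfg, zero_rate_per_trait=0.05, seed=32
        )
        panel, report = tp.prepare_trait_panel(pt, seed=33)
        assert panel.blups.shape[0] <= 80
        assert set(panel.h2) == set(panel.blups.columns)
        assert all(0 <= h <= 1 for h in panel.h2.values())
        # transformed columns keep >= 80% of lines
        frac = panel.transformed.notna().mean()
        assert (frac >= 0.8).all()
        # BLUPs correlate with true genetic values
        common = [t for t in truth.genetic_values.columns if t in panel.blups.columns]
        r = np.corrcoef(
            panel.blups[common[0]].dropna(),
            truth.genetic_values.loc[panel.blups[common[0]].dropna().index, common[0]],
        )[0, 1]
        assert r > 0.5
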