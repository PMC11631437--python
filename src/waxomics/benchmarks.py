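"""Self-contained benchmark studies exercising the pipeline end to end.

Each function simulates its own data with the bundled generator, runs the
relevant estimator(s), and returns summary numbers.  The studies double as
the package's acceptance checks: oracle equivalences against closed forms
and brute-force refits, null calibration of the scans and the hotspot
window procedure, parameter recovery (planted QTLs, causal genes,
heritability, hotspot clusters), and the behavior of the random-forest
predictor.  Problem sizes are desk scale — hundreds of lines, thousands of
markers — chosen so each study runs in seconds to a couple of minutes; see
docs/methods.md for the rationale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import assoc, hotspots as hsp, integrate, predict as pr, synthdata as sd, traitprep as tp
from ._utils import derive_seed

DEFAULT_CHROMS = (("1", 100_000_000), ("2", 100_000_000))


# ---------------------------------------------------------------------------
# Trait registry bookkeeping
# ---------------------------------------------------------------------------


def trait_registry_counts() -> dict[str, int]:
    reg = sd.default_trait_registry()
    return {
        "n_compounds": int((~reg["is_sum"]).sum()),
        "n_traits_total": int(len(reg)),
        "n_sum_traits": int(reg["is_sum"].sum()),
    }


# ---------------------------------------------------------------------------
# Oracle equivalences
# ---------------------------------------------------------------------------


def fisher_oracle_error(n_grid: int = 40) -> float:
    """Max |fisher_combine - closed form| over a log-spaced p grid."""
    ps = np.logspace(-12, 0, n_grid)
    ps[-1] = 1.0
    err = 0.0
    for p1 in ps:
        for p2 in ps:
            X = -2.0 * (np.log(p1) + np.log(p2))
            closed = np.exp(-X / 2.0) * (1.0 + X / 2.0)
            err = max(err, abs(integrate.fisher_combine(p1, p2) - closed))
    return float(err)


def scan_vs_ols_error(seed: int = 0, n_lines: int = 150, n_snps: int = 300) -> dict[str, float]:
    """Max |p - OLS p| for GWAS and TWAS under identity kinship."""
    rng = np.random.default_rng(derive_seed(seed, 11))
    gm = sd.simulate_population(n_lines, n_snps, seed=derive_seed(seed, 12))
    y = rng.standard_normal(n_lines)
    Kid = assoc.KinshipMatrix(np.eye(n_lines), gm.line_ids)
    tab = assoc.gwas_scan(y, gm, Kid, mode="p3d")
    gwas_err = 0.0
    X = gm.dosages.astype(float)
    for j in range(0, n_snps, 7):
        p_ols = stats.linregress(X[:, j], y).pvalue
        gwas_err = max(gwas_err, abs(p_ols - tab["p"].iloc[j]))
    expr = pd.DataFrame(
        rng.standard_normal((n_lines, 40)),
        index=gm.line_ids,
        columns=[f"g{j}" for j in range(40)],
    )
    ttab = assoc.twas_scan(y, expr, Kid, per_gene_reml=False)
    twas_err = max(
        abs(stats.linregress(expr.iloc[:, j], y).pvalue - ttab["p"].iloc[j]) for j in range(40)
    )
    return {"gwas_vs_ols_max_err": float(gwas_err), "twas_vs_ols_max_err": float(twas_err)}


def sdr_oracle_error(seed: int = 0, n: int = 25, p: int = 4) -> float:
    """Max |SDR - brute-force leave-one-out refit| on a random design."""
    rng = np.random.default_rng(derive_seed(seed, 21))
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    y = X @ rng.standard_normal(p) + rng.standard_normal(n)
    _, _, sdr = tp.screen_outliers_sdr(y, X)
    err = 0.0
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        beta = np.linalg.lstsq(X[mask], y[mask], rcond=None)[0]
        resid = y[mask] - X[mask] @ beta
        mse_i = float(resid @ resid) / (n - 1 - p)
        h_ii = float(X[i] @ np.linalg.inv(X.T @ X) @ X[i])
        e_i = y[i] - X[i] @ np.linalg.lstsq(X, y, rcond=None)[0]
        t_i = e_i / np.sqrt(mse_i * (1.0 - h_ii))
        err = max(err, abs(t_i - sdr[i]))
    return float(err)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def gwas_null_calibration(
    seed: int = 0, n_lines: int = 250, n_snps: int = 4000, n_reps: int = 2
) -> dict[str, float]:
    """lambda_GC and empirical type-I error of a null GWAS with structure.

    The trait carries a polygenic background (drawn from the kinship) but no
    individual causal SNP; p-values from ``n_reps`` independent panels are
    pooled for the rejection rate.
    """
    pvs, lambdas = [], []
    for rep in range(n_reps):
        gm = sd.simulate_population(
            n_lines, n_snps, n_subpops=3, fst=0.08, seed=derive_seed(seed, 31, rep)
        )
        K = assoc.compute_kinship(gm)
        rng = np.random.default_rng(derive_seed(seed, 32, rep))
        L = np.linalg.cholesky(K.values + 1e-8 * np.eye(n_lines))
        y = L @ rng.standard_normal(n_lines) + rng.standard_normal(n_lines)
        tab = assoc.gwas_scan(y, gm, K, mode="p3d")
        pvs.append(tab["p"].to_numpy())
        lambdas.append(assoc.genomic_inflation(pvs[-1]))
    pv = np.concatenate(pvs)
    return {
        "lambda_gc": float(np.mean(lambdas)),
        "gwas_type1_at_0.01": float(np.mean(pv < 0.01)),
    }


def twas_null_calibration(
    seed: int = 0, n_lines: int = 200, n_genes: int = 400, n_reps: int = 3
) -> dict[str, float]:
    pvs = []
    for rep in range(n_reps):
        gm = sd.simulate_population(n_lines, 600, seed=derive_seed(seed, 41, rep))
        layout = sd.simulate_gene_models(n_genes=n_genes, seed=derive_seed(seed, 42, rep))
        ex = sd.simulate_expression(gm, layout, cis_h2=0.3, seed=derive_seed(seed, 43, rep))
        resid = tp.residualize_expression(ex.line_means(), k_factors=5, screen_outliers=False)
        K = assoc.compute_kinship(gm)
        rng = np.random.default_rng(derive_seed(seed, 44, rep))
        y = rng.standard_normal(n_lines)
        tab = assoc.twas_scan(y, resid, K, per_gene_reml=True)
        pvs.append(tab["p"].to_numpy())
    pv = np.concatenate(pvs)
    ks = stats.kstest(pv, "uniform").pvalue
    return {"twas_type1_at_0.01": float(np.mean(pv < 0.01)), "twas_null_ks_p": float(ks)}


def hotspot_null_calibration(
    seed: int = 0, n_reps: int = 100, n_loci: int = 60, q: float = 0.95
) -> dict[str, float]:
    """Flagged-window fraction under uniformly placed loci.

    For integer counts the flagged fraction is bounded by (1 - q) plus the
    probability mass at the threshold count (the quantile granularity); both
    the fraction and the bound are returned, averaged over replicates.
    """
    rng = np.random.default_rng(derive_seed(seed, 51))
    fracs, bounds = [], []
    classes = list(sd.WAX_CLASSES)
    for _ in range(n_reps):
        loci = [
            integrate.Locus(
                trait_id=f"t{i}",
                chrom=str(rng.integers(1, 3)),
                pos=int(rng.integers(0, 100_000_000)),
                p=1e-6,
                peak_snp="s",
                wax_class=classes[rng.integers(0, 6)],
            )
            for i in range(n_loci)
        ]
        wc = hsp.window_counts(loci, DEFAULT_CHROMS)
        counts = wc["count"].to_numpy()
        thr = hsp.empirical_threshold(counts, q)
        fracs.append(float(np.mean(counts >= thr)))
        bounds.append((1.0 - q) + float(np.mean(counts == thr)))
    return {
        "hotspot_flagged_frac": float(np.mean(fracs)),
        "hotspot_flagged_bound": float(np.mean(bounds)),
    }


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------


def gwas_power_study(
    seed: int = 0,
    n_reps: int = 25,
    n_lines: int = 300,
    n_snps: int = 2000,
    qtl_var: float = 0.10,
    top_frac: float = 2e-5,
) -> dict[str, float]:
    """Fraction of replicates in which a planted QTL reaches the top SNP set.

    A single SNP of MAF ~ 0.3 explains ``qtl_var`` of the phenotypic
    variance; at desk-scale SNP counts the top-fraction rule selects a single
    SNP, so success means the causal marker itself is the minimum-p SNP.
    """
    hits = 0
    for rep in range(n_reps):
        gm = sd.simulate_population(n_lines, n_snps, seed=derive_seed(seed, 61, rep))
        rng = np.random.default_rng(derive_seed(seed, 62, rep))
        maf = gm.snp_meta["maf"].to_numpy()
        cands = np.flatnonzero((maf > 0.25) & (maf < 0.35))
        causal = int(rng.choice(cands))
        x = gm.dosages[:, causal].astype(float)
        xs = (x - x.mean()) / x.std()
        y = np.sqrt(qtl_var) * xs + np.sqrt(1 - qtl_var) * rng.standard_normal(n_lines)
        K = assoc.compute_kinship(gm)
        tab = assoc.gwas_scan(y, gm, K, mode="p3d")
        from ._utils import top_k

        k = top_k(top_frac, n_snps)
        top_ids = set(tab.nsmallest(k, "p")["feature_id"])
        if gm.snp_meta["snp_id"].iloc[causal] in top_ids:
            hits += 1
    return {"gwas_qtl_top_rate": hits / n_reps}


def twas_power_study(
    seed: int = 0,
    n_reps: int = 25,
    n_lines: int = 300,
    n_genes: int = 300,
    expr_var: float = 0.30,
) -> dict[str, float]:
    """Fraction of replicates where the causal gene is the min-p TWAS gene."""
    hits = 0
    for rep in range(n_reps):
        gm = sd.simulate_population(n_lines, 800, seed=derive_seed(seed, 71, rep))
        layout = sd.simulate_gene_models(n_genes=n_genes, seed=derive_seed(seed, 72, rep))
        ex = sd.simulate_expression(gm, layout, cis_h2=0.4, seed=derive_seed(seed, 73, rep))
        rng = np.random.default_rng(derive_seed(seed, 74, rep))
        g = int(rng.integers(0, n_genes))
        e = ex.line_means().iloc[:, g].to_numpy()
        es = (e - e.mean()) / e.std()
        y = np.sqrt(expr_var) * es + np.sqrt(1 - expr_var) * rng.standard_normal(n_lines)
        resid = tp.residualize_expression(ex.line_means(), k_factors=5, screen_outliers=False)
        K = assoc.compute_kinship(gm)
        tab = assoc.twas_scan(y, resid, K, per_gene_reml=True)
        if tab.sort_values("p")["feature_id"].iloc[0] == ex.gene_ids[g]:
            hits += 1
    return {"twas_gene_top_rate": hits / n_reps}


def group1_recovery_study(
    seed: int = 0, n_reps: int = 20, n_lines: int = 300, n_snps: int = 1200, n_genes: int = 300
) -> dict[str, float]:
    """A gene with coupled cis-eQTL trait effect and GWAS signal lands in group 1.

    The trait draws on both the gene's expression and its cis SNP, so GWAS
    (locus within +/-200 kb), TWAS (top gene) and the Fisher-combined test
    should all flag the same gene for the same trait.
    """
    hits = 0
    for rep in range(n_reps):
        gm = sd.simulate_population(n_lines, n_snps, seed=derive_seed(seed, 81, rep))
        layout = sd.simulate_gene_models(n_genes=n_genes, seed=derive_seed(seed, 82, rep))
        ex = sd.simulate_expression(gm, layout, cis_h2=0.6, seed=derive_seed(seed, 83, rep))
        rng = np.random.default_rng(derive_seed(seed, 84, rep))
        cis = ex.truth.cis_assignments
        with_cis = cis[cis["has_cis"]].index.to_numpy()
        gi = int(rng.choice(with_cis))
        snp_j = int(cis["snp_index"].iloc[gi])
        e = ex.line_means().iloc[:, gi].to_numpy()
        es = (e - e.mean()) / e.std()
        x = gm.dosages[:, snp_j].astype(float)
        xs = (x - x.mean()) / max(x.std(), 1e-12)
        y = 0.55 * es + 0.45 * xs + 0.55 * rng.standard_normal(n_lines)
        K = assoc.compute_kinship(gm)
        resid = tp.residualize_expression(ex.line_means(), k_factors=5, screen_outliers=False)
        gtab = assoc.gwas_scan(y, gm, K, mode="p3d", trait_id="T")
        ttab = assoc.twas_scan(y, resid, K, per_gene_reml=False, trait_id="T")
        ftab = integrate.fct_scan(gtab, ttab, layout)
        loci = integrate.declare_gwas_loci(gtab, trait_id="T")
        cands = integrate.select_candidates(loci, layout, ttab, ftab)
        groups = integrate.confidence_groups({"T": cands}, class_map={"T": "WE"})
        if ex.gene_ids[gi] in groups.group1:
            hits += 1
    return {"group1_recovery_rate": hits / n_reps}


def heritability_recovery_study(
    seed: int = 0, n_lines: int = 200, reps_per_level: int = 3
) -> dict[str, float]:
    """Mean absolute error of estimated line-mean h2 against the truth.

    Traits are simulated at design-implied h2 of 0.2, 0.5 and 0.8 (six
    compounds of one class per replicate), fit with the full REML model, and
    summarized by h2 = s2_G / (s2_G + s2_GE/e + s2_eps/(e r)).
    """
    level_specs = {
        0.8: sd.TraitTruthSpec(sigma2_G=1.0, sigma2_GE=0.3, sigma2_resid=0.4),
        0.5: sd.TraitTruthSpec(sigma2_G=1.0, sigma2_GE=1.0, sigma2_resid=2.0),
        0.2: sd.TraitTruthSpec(sigma2_G=1.0, sigma2_GE=3.0, sigma2_resid=10.0),
    }
    errs = []
    cfg = sd.ClassConfig(class_counts={"PA": 6})
    for li, (target, spec) in enumerate(level_specs.items()):
        for rep in range(reps_per_level):
            gm = sd.simulate_population(n_lines, 400, seed=derive_seed(seed, 91, li, rep))
            pt, _, truth = sd.simulate_traits_and_gc(
                gm,
                None,
                None,
                class_config=cfg,
                truth_spec=spec,
                zero_rate_per_trait=0.0,
                seed=derive_seed(seed, 92, li, rep),
            )
            for trait in truth.causal_snps:
                vc, _, _ = tp.fit_trait_mixed_model(pt, trait)
                e_bar, r_bar = tp.design_harmonic_means(pt, trait)
                h2 = tp.line_mean_heritability(vc, e_bar, r_bar)
                errs.append(abs(h2 - truth.implied_h2[trait]))
    return {"h2_mae": float(np.mean(errs)), "h2_n_traits": len(errs)}


def hotspot_recovery_study(
    seed: int = 0, n_reps: int = 50, n_background: int = 40
) -> dict[str, float]:
    """Recovery of a planted 5-locus, 3-class cluster as one interclass hotspot."""
    rng = np.random.default_rng(derive_seed(seed, 101))
    classes = list(sd.WAX_CLASSES)
    hits = 0
    for _ in range(n_reps):
        loci = [
            integrate.Locus(
                trait_id=f"bg{i}",
                chrom=str(rng.integers(1, 3)),
                pos=int(rng.integers(0, 100_000_000)),
                p=1e-6,
                peak_snp="s",
                wax_class=classes[rng.integers(0, 6)],
            )
            for i in range(n_background)
        ]
        center = int(rng.integers(1_000_000, 99_000_000))
        cluster_cls = list(rng.choice(classes, size=3, replace=False))
        planted_pos = [center + int(d) for d in rng.integers(0, 100_000, size=5)]
        for i, p in enumerate(planted_pos):
            loci.append(
                integrate.Locus(
                    trait_id=f"pl{i}",
                    chrom="1",
                    pos=p,
                    p=1e-9,
                    peak_snp="s",
                    wax_class=cluster_cls[i % 3],
                )
            )
        hs = hsp.call_hotspots(loci, DEFAULT_CHROMS, mode="interclass")
        containing = [
            h for h in hs if h.chrom == "1" and all(h.start <= p < h.end for p in planted_pos)
        ]
        if len(containing) == 1:
            hits += 1
    return {"hotspot_recovery_rate": hits / n_reps}


# ---------------------------------------------------------------------------
# Prediction behavior
# ---------------------------------------------------------------------------


def rf_noiseless_study(seed: int = 0, n_trees: int = 500, n_repeats: int = 3) -> dict[str, float]:
    """CV predictive ability when g_c is a noiseless function of 6 trait values."""
    gm = sd.simulate_population(300, 600, seed=derive_seed(seed, 111))
    spec = sd.TraitTruthSpec(gc_noise_sd=0.0)
    _, _, truth = sd.simulate_traits_and_gc(
        gm, None, None, truth_spec=spec, zero_rate_per_trait=0.0, seed=derive_seed(seed, 112)
    )
    cfg = pr.RFConfig(n_trees=n_trees, mtry=10, n_repeats=n_repeats, seed=derive_seed(seed, 113))
    rep = pr.rf_cross_validate(truth.genetic_values, truth.gc_genetic, cfg)
    return {"rf_noiseless_ability": rep.mean_ability}


def rf_null_study(
    seed: int = 0, n_trees: int = 150, n_repeats: int = 50, n_null_draws: int = 5
) -> dict[str, float]:
    """CV predictive ability when g_c is independent of every feature.

    A single null target confounds the expected null ability with that
    draw's chance association (and the mild negative bias of cross-validated
    correlations), so the repeats are spread over several independent null
    targets and pooled.
    """
    gm = sd.simulate_population(300, 600, seed=derive_seed(seed, 121))
    _, _, truth = sd.simulate_traits_and_gc(
        gm, None, None, zero_rate_per_trait=0.0, seed=derive_seed(seed, 122)
    )
    rng = np.random.default_rng(derive_seed(seed, 123))
    reps_per_draw = max(1, n_repeats // n_null_draws)
    abilities = []
    for d in range(n_null_draws):
        y = pd.Series(rng.standard_normal(300), index=truth.genetic_values.index)
        cfg = pr.RFConfig(
            n_trees=n_trees, mtry=10, n_repeats=reps_per_draw, seed=derive_seed(seed, 124, d)
        )
        abilities.extend(pr.rf_cross_validate(truth.genetic_values, y, cfg).per_repeat_ability)
    return {"rf_null_ability": float(np.mean(abilities))}


def rf_importance_study(
    seed: int = 0, n_runs: int = 20, n_trees: int = 200, n: int = 300, m: int = 60
) -> dict[str, float]:
    """Fraction of runs in which all 6 causal features rank in the top 10."""
    hits = 0
    for run in range(n_runs):
        rng = np.random.default_rng(derive_seed(seed, 131, run))
        X = pd.DataFrame(rng.standard_normal((n, m)), columns=[f"f{j}" for j in range(m)])
        y = pd.Series(X.iloc[:, :6].sum(axis=1).to_numpy() + 0.5 * rng.standard_normal(n))
        cfg = pr.RFConfig(n_trees=n_trees, mtry=10, seed=derive_seed(seed, 132, run))
        imp = pr.rf_importance(X, y, cfg)
        top10 = set(imp["feature"].head(10))
        if all(f"f{j}" in top10 for j in range(6)):
            hits += 1
    return {"rf_importance_top10_rate": hits / n_runs}
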