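"""Trait QC, BLUPs, heritability, transformation, expression residualization.

Pipeline order (matching the study design of a two-environment augmented
field trial with GC-FID laboratory structure):

1. drop traits undetected (zero) in more than 40% of lines;
2. impute remaining zeros from Uniform(0, environment minimum positive value);
3. screen plot-level outliers by Studentized deleted residuals (SDR) at a
   Bonferroni-corrected alpha = 0.05;
4. REML fit of the full random-terms model -> variance components, line BLUPs;
5. line-mean heritability from the variance components;
6. Box-Cox transform of the BLUPs ("convenient lambda");
7. second SDR screen on the transformed BLUPs.

The expression matrix follows an analogous path, with latent-factor
residualization (a truncated-SVD stand-in for PEER) instead of the GC-FID
terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mixedmodel import MixedModelFit, VarianceComponents, fit_variance_components

RANDOM_TERMS = ("genotype", "env", "gxe", "block", "col", "instrument", "instr_col")

CONVENIENT_LAMBDAS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0)


@dataclass
class QCReport:
    """Log of the QC decisions taken while preparing a trait panel."""

    traits_dropped: dict[str, float] = field(default_factory=dict)  # trait -> zero fraction
    outliers_removed: dict[str, dict[str, list]] = field(default_factory=dict)
    imputation_log: dict[str, dict[str, dict]] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "traits_dropped": self.traits_dropped,
            "outliers_removed": self.outliers_removed,
            "imputation_log": self.imputation_log,
        }


@dataclass
class TraitPanel:
    """Line-level trait panel: BLUPs, transformed BLUPs, lambda, h2, classes."""

    blups: pd.DataFrame  # line x trait, untransformed
    transformed: pd.DataFrame  # line x trait, Box-Cox + outlier screen (NaN where removed)
    lambdas: dict[str, float]
    h2: dict[str, float]
    classes: dict[str, str]
    variance_components: dict[str, VarianceComponents] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Zero handling
# ---------------------------------------------------------------------------


def line_zero_fraction(plot_table: pd.DataFrame, trait_id: str) -> float:
    """Fraction of lines whose every plot of this trait is zero."""
    sub = plot_table[plot_table["trait_id"] == trait_id]
    per_line = sub.groupby("line_id")["value"].max()
    return float((per_line == 0).mean())


def filter_detectable_traits(
    plot_table: pd.DataFrame, max_zero_frac: float = 0.40
) -> tuple[pd.DataFrame, QCReport]:
    """Drop traits undetected in strictly more than ``max_zero_frac`` of lines.

    A line counts as zero for a trait when all of its plots are zero; the
    fraction is computed over lines, and the inequality is strict ("over 40%"),
    so a trait at exactly the threshold is retained.
    """
    if plot_table.empty:
        raise ValueError("empty plot table")
    report = QCReport()
    keep = []
    for trait in plot_table["trait_id"].unique():
        zf = line_zero_fraction(plot_table, trait)
        if zf > max_zero_frac:
            report.traits_dropped[trait] = zf
        else:
            keep.append(trait)
    if not keep:
        raise ValueError("all traits removed by the zero filter")
    return plot_table[plot_table["trait_id"].isin(keep)].copy(), report


def impute_zero_abundances(plot_table: pd.DataFrame, seed: int = 0) -> tuple[pd.DataFrame, QCReport]:
    """Replace zeros by draws from Uniform(0, m), m the (trait, env) minimum positive.

    The draw is strictly inside the open interval (0, m).  A (trait, env) cell
    that is entirely zero cannot bound the uniform and raises.
    """
    rng = np.random.default_rng(seed)
    out = plot_table.copy()
    report = QCReport()
    for (trait, env), idx in out.groupby(["trait_id", "env"]).groups.items():
        vals = out.loc[idx, "value"].to_numpy(float)
        zeros = vals == 0
        if not zeros.any():
            continue
        pos = vals[vals > 0]
        if pos.size == 0:
            raise ValueError(f"trait {trait!r} in env {env} is entirely zero; cannot impute")
        m = float(pos.min())
        draws = rng.uniform(0.0, m, size=int(zeros.sum()))
        while (draws == 0).any():  # keep the interval open
            draws[draws == 0] = rng.uniform(0.0, m, size=int((draws == 0).sum()))
        vals[zeros] = draws
        out.loc[idx, "value"] = vals
        report.imputation_log.setdefault(str(trait), {})[str(env)] = {
            "n_imputed": int(zeros.sum()),
            "upper_bound": m,
        }
    return out, report


# ---------------------------------------------------------------------------
# Mixed model per trait
# ---------------------------------------------------------------------------


def _dummy(codes: pd.Series) -> tuple[np.ndarray, list]:
    levels, inv = np.unique(codes.to_numpy(), return_inverse=True)
    Z = np.zeros((len(codes), len(levels)))
    Z[np.arange(len(codes)), inv] = 1.0
    return Z, list(levels)


def build_design(sub: pd.DataFrame, random_terms=RANDOM_TERMS):
    """Design matrices for the trait model from a single-trait plot table."""
    term_keys = {
        "genotype": sub["line_id"],
        "env": sub["env"].astype(str),
        "gxe": sub["env"].astype(str) + ":" + sub["line_id"],
        "block": sub["env"].astype(str) + ":" + sub["block_id"].astype(str),
        "col": sub["env"].astype(str) + ":" + sub["column_id"].astype(str),
        "instrument": sub["instrument_id"].astype(str),
        "instr_col": sub["instrument_id"].astype(str) + ":" + sub["instrument_column_id"].astype(str),
    }
    Z_list, names, levels = [], [], {}
    for term in random_terms:
        if term not in term_keys:
            raise ValueError(f"unknown random term {term!r}")
        Z, lv = _dummy(term_keys[term])
        if Z.shape[1] < 2 and term != "genotype":
            continue  # single-level term carries no variance
        Z_list.append(Z)
        names.append(term)
        levels[term] = lv
    X = np.ones((len(sub), 1))
    if "is_check" in sub.columns and sub["is_check"].any():
        X = np.column_stack([X, sub["is_check"].astype(float).to_numpy()])
    return X, Z_list, names, levels


def fit_trait_mixed_model(
    plot_table: pd.DataFrame,
    trait_id: str,
    random_terms=RANDOM_TERMS,
) -> tuple[VarianceComponents, pd.Series, pd.Series]:
    """REML fit of one trait's mixed model.

    Fixed effects are the grand mean and (when present) the check-line
    indicator; the random terms default to genotype, environment, GxE,
    block-in-env, column-in-env, instrument, and column-in-instrument.
    Returns (variance components, line BLUPs, conditional plot residuals).
    Check plots contribute to estimation but are excluded from the BLUP
    output.
    """
    sub = plot_table[plot_table["trait_id"] == trait_id]
    if sub.empty:
        raise ValueError(f"trait {trait_id!r} not in plot table")
    y = sub["value"].to_numpy(float)
    X, Z_list, names, levels = build_design(sub, random_terms)
    fit = fit_variance_components(y, X, Z_list, names)
    blup = pd.Series(fit.blups["genotype"], index=levels["genotype"], name=trait_id)
    if "is_check" in sub.columns:
        checks = set(sub.loc[sub["is_check"], "line_id"])
        blup = blup[~blup.index.isin(checks)]
    resid = pd.Series(fit.residuals, index=sub.index, name=trait_id)
    return fit.vc, blup, resid


# ---------------------------------------------------------------------------
# Studentized deleted residuals
# ---------------------------------------------------------------------------


def screen_outliers_sdr(
    response: np.ndarray, design: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-pass outlier screen by Studentized deleted residuals.

    Observation i is flagged when |t_i| exceeds the two-sided t quantile at
    the Bonferroni level alpha / n with df = n - p - 1, where
    t_i = e_i / sqrt(MSE_(-i) (1 - h_ii)).  Observations with leverage
    h_ii ~= 1 carry no deletion residual; they are excluded from the screen
    and reported as NaN.

    Returns (kept mask, removed indices, SDR values).
    """
    y = np.asarray(response, float)
    X = np.atleast_2d(np.asarray(design, float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > p + 1 for deleted residuals")
    Q, R = np.linalg.qr(X)
    h = np.einsum("ij,ij->i", Q, Q)
    e = y - Q @ (Q.T @ y)
    sse = float(e @ e)
    sdr = np.full(n, np.nan)
    ok = h < 1.0 - 1e-10
    denom = sse * (1.0 - h[ok]) - e[ok] ** 2
    denom = np.clip(denom, 1e-300, None)
    sdr[ok] = e[ok] * np.sqrt((n - p - 1) / denom)
    cut = stats.t.ppf(1.0 - alpha / (2.0 * n), df=n - p - 1)
    removed = np.flatnonzero(ok & (np.abs(sdr) > cut))
    kept = np.ones(n, bool)
    kept[removed] = False
    return kept, removed, sdr


# ---------------------------------------------------------------------------
# Heritability
# ---------------------------------------------------------------------------


def harmonic_mean(x) -> float:
    x = np.asarray(x, float)
    if (x <= 0).any():
        raise ValueError("harmonic mean requires positive values")
    return float(len(x) / np.sum(1.0 / x))


def line_mean_heritability(vc: VarianceComponents, n_envs: float, plots_per_line: float) -> float:
    """Line-mean heritability h2 = s2_G / (s2_G + s2_GE/e + s2_eps/(e*r)).

    ``n_envs`` and ``plots_per_line`` are the (harmonic mean) number of
    environments and total plots per line of the trial.  The result is
    clamped to [0, 1].
    """
    g = vc["genotype"]
    ge = vc.components.get("gxe", 0.0)
    e2 = vc["residual"]
    denom = g + ge / n_envs + e2 / (n_envs * plots_per_line)
    if denom <= 0:
        raise ValueError("all variance components are zero; heritability undefined")
    return float(np.clip(g / denom, 0.0, 1.0))


def design_harmonic_means(plot_table: pd.DataFrame, trait_id: str) -> tuple[float, float]:
    """Harmonic means of environment count and total plot count per line."""
    sub = plot_table[plot_table["trait_id"] == trait_id]
    envs = sub.groupby("line_id")["env"].nunique()
    plots = sub.groupby("line_id").size()
    return harmonic_mean(envs), harmonic_mean(plots)


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------


def boxcox_transform(
    blups: np.ndarray, grid: np.ndarray | None = None
) -> tuple[np.ndarray, float, float]:
    """Box-Cox transform with a "convenient" lambda.

    lambda maximizes the profile log-likelihood (intercept-only model) on the
    grid -2..2 step 0.1 and is then snapped to the nearest member of
    {-2, -1, -0.5, 0, 0.5, 1, 2} that lies within the 95% profile-likelihood
    interval.  Inputs must be positive; non-positive BLUPs are shifted by
    min + epsilon first and the shift is returned.

    Returns (transformed, lambda, shift).
    """
    y = np.asarray(blups, float)
    y = y[~np.isnan(y)] if np.isnan(y).any() else y
    shift = 0.0
    if (np.asarray(blups, float) <= 0).any():
        mn = float(np.nanmin(blups))
        shift = -mn + 1e-6 * (float(np.nanmax(blups)) - mn + 1.0)
    yv = np.asarray(blups, float) + shift
    obs = yv[~np.isnan(yv)]
    if (obs <= 0).any():
        raise ValueError("non-positive values remain after shifting")
    grid = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.1), 10) if grid is None else grid
    llf = np.array([stats.boxcox_llf(l, obs) for l in grid])
    i = int(np.argmax(llf))
    lam = float(grid[i])
    ci_cut = llf[i] - stats.chi2.ppf(0.95, df=1) / 2.0
    in_ci = [c for c in CONVENIENT_LAMBDAS if stats.boxcox_llf(c, obs) >= ci_cut]
    if in_ci:
        lam = min(in_ci, key=lambda c: (abs(c - lam), c))
    if lam == 0.0:
        out = np.log(yv)
    else:
        out = (np.power(yv, lam) - 1.0) / lam
    return out, lam, shift


# ---------------------------------------------------------------------------
# Expression residualization (PEER stand-in)
# ---------------------------------------------------------------------------


def residualize_expression(
    expression: pd.DataFrame,
    k_factors: int = 20,
    screen_outliers: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Remove k latent factors from a line x gene expression matrix.

    The matrix is column-standardized, the top ``k_factors`` singular vectors
    (a probabilistic-PCA-style stand-in for PEER) are removed, and each gene is
    then screened for outliers with Studentized deleted residuals
    (intercept-only design); flagged entries become NaN.  ``k_factors <= 0``
    returns the standardized matrix unchanged.
    """
    M = expression.to_numpy(float)
    mu = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (M - mu) / sd
    if k_factors > 0:
        if k_factors >= min(Z.shape):
            raise ValueError("k_factors must be < min(n_lines, n_genes)")
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        Z = Z - (U[:, :k_factors] * s[:k_factors]) @ Vt[:k_factors]
    out = pd.DataFrame(Z, index=expression.index, columns=expression.columns)
    if screen_outliers:
        ones = np.ones((Z.shape[0], 1))
        for j, col in enumerate(out.columns):
            kept, removed, _ = screen_outliers_sdr(Z[:, j], ones, alpha=alpha)
            if removed.size:
                out.iloc[removed, j] = np.nan
    return out


# ---------------------------------------------------------------------------
# Full panel pipeline
# ---------------------------------------------------------------------------


def prepare_trait_panel(
    plot_table: pd.DataFrame,
    seed: int = 0,
    max_zero_frac: float = 0.40,
    alpha: float = 0.05,
    random_terms=RANDOM_TERMS,
) -> tuple[TraitPanel, QCReport]:
    """Run the full QC -> BLUP -> transform pipeline on a plot table."""
    filtered, rep_filter = filter_detectable_traits(plot_table, max_zero_frac)
    imputed, rep_imp = impute_zero_abundances(filtered, seed=seed)
    report = QCReport(
        traits_dropped=rep_filter.traits_dropped, imputation_log=rep_imp.imputation_log
    )

    blups, transformed, lambdas, h2, classes, vcs = {}, {}, {}, {}, {}, {}
    for trait in imputed["trait_id"].unique():
        sub = imputed[imputed["trait_id"] == trait]
        # plot-level SDR screen on a fixed-effects working model of the design
        X_work = _working_design(sub)
        kept, removed, sdr = screen_outliers_sdr(sub["value"].to_numpy(float), X_work, alpha)
        report.outliers_removed.setdefault(trait, {})["plot"] = [
            [int(i), float(sdr[i])] for i in removed
        ]
        clean = sub.iloc[np.flatnonzero(kept)]
        vc, blup, _ = fit_trait_mixed_model(
            pd.concat([clean], ignore_index=False), trait, random_terms
        )
        vcs[trait] = vc
        e_bar, r_bar = design_harmonic_means(clean, trait)
        h2[trait] = line_mean_heritability(vc, e_bar, r_bar)
        blups[trait] = blup
        grand_mean = clean["value"].mean()
        tvals, lam, _ = boxcox_transform(blup.to_numpy() + grand_mean)
        lambdas[trait] = lam
        tser = pd.Series(tvals, index=blup.index)
        kept2, removed2, sdr2 = screen_outliers_sdr(tvals, np.ones((len(tvals), 1)), alpha)
        report.outliers_removed[trait]["blup"] = [
            [str(tser.index[i]), float(sdr2[i])] for i in removed2
        ]
        tser.iloc[removed2] = np.nan
        transformed[trait] = tser
        if "wax_class" in sub.columns:
            classes[trait] = sub["wax_class"].iloc[0]

    panel = TraitPanel(
        blups=pd.DataFrame(blups),
        transformed=pd.DataFrame(transformed),
        lambdas=lambdas,
        h2=h2,
        classes=classes,
        variance_components=vcs,
    )
    return panel, report


def _working_design(sub: pd.DataFrame) -> np.ndarray:
    """Fixed-effects working design (dummies for the model terms) for SDR."""
    cols = [np.ones(len(sub))]
    for key in (
        sub["line_id"],
        sub["env"].astype(str),
        sub["env"].astype(str) + ":" + sub["block_id"].astype(str),
        sub["instrument_id"].astype(str),
    ):
        Z, _ = _dummy(key)
        if Z.shape[1] > 1:
            cols.append(Z[:, 1:])  # drop one level per factor
    X = np.column_stack(cols)
    # guard: keep the screen well-posed (n > p + 1)
    if X.shape[0] <= X.shape[1] + 1:
        X = np.ones((len(sub), 1))
    return X
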