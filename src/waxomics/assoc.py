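"""Kinship, principal components, model selection, and mixed-model GWAS/TWAS.

The association model is y = Xb + s*beta + u + e with u ~ N(0, sigma2_g K):
a single-marker (or single-gene-expression) fixed effect tested by a Wald
test under a kinship-controlled mixed model.  Two variance-component modes
are offered: "p3d" estimates the variance ratio once on the null model and
reuses it for every marker (fast, the common GWAS default), while "exact"
re-optimizes per marker (the TWAS default).  Variance explained is summarized
by the likelihood-ratio R^2, 1 - exp(-(2/n)(LL_full - LL_null)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mixedmodel import KinshipModel
from .synthdata import GenotypeMatrix


@dataclass
class KinshipMatrix:
    values: np.ndarray
    line_ids: list[str]
    method: str = "vanraden"


@dataclass
class ModelSpec:
    covariates: list[str]
    kinship: bool
    bic: float


def filter_snps(gm: GenotypeMatrix, maf_min: float = 0.05, dr2_min: float = 0.80) -> GenotypeMatrix:
    """Retain biallelic SNPs with MAF >= maf_min and DR2 >= dr2_min."""
    keep = (gm.snp_meta["maf"].to_numpy() >= maf_min) & (gm.snp_meta["dr2"].to_numpy() >= dr2_min)
    return GenotypeMatrix(
        dosages=gm.dosages[:, keep],
        snp_meta=gm.snp_meta.loc[keep].reset_index(drop=True),
        line_ids=list(gm.line_ids),
    )


def compute_kinship(gm: GenotypeMatrix, method: str = "vanraden") -> KinshipMatrix:
    """VanRaden kinship: centered cross-product scaled by 2 sum p_j (1 - p_j).

    Monomorphic SNPs carry no relatedness information and are excluded with a
    warning.
    """
    if method != "vanraden":
        raise ValueError(f"unknown kinship method {method!r}")
    X = gm.dosages.astype(float)
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(f"excluding {int((~poly).sum())} monomorphic SNPs from kinship")
        X, p = X[:, poly], p[poly]
    W = X - 2.0 * p
    K = (W @ W.T) / (2.0 * np.sum(p * (1.0 - p)))
    return KinshipMatrix(values=K, line_ids=list(gm.line_ids), method=method)


def compute_pcs(gm: GenotypeMatrix, k: int) -> np.ndarray:
    """Top-k principal-component scores of the centered dosage matrix.

    Each component's sign is fixed so its largest-magnitude loading is
    positive.  ``k <= 0`` returns an empty (n, 0) matrix.
    """
    n = gm.n_lines
    if k <= 0:
        return np.empty((n, 0))
    if k >= n:
        raise ValueError("k must be < n_lines")
    X = gm.dosages.astype(float)
    X = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :k] * s[:k]
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            scores[:, j] *= -1.0
    return scores


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------


def bic(loglik: float, n_params: int, n: int) -> float:
    return -2.0 * loglik + n_params * np.log(n)


def select_model_bic(
    trait_values: np.ndarray,
    candidate_covariate_sets: dict[str, np.ndarray | None],
    kinship: KinshipMatrix,
) -> ModelSpec:
    """Pick the null GWAS model minimizing BIC over candidate covariate sets.

    Every candidate includes the kinship random effect; candidates differ in
    their fixed covariates (e.g. none, flowering time, principal components).
    BIC = -2 LL + q ln n with q counting fixed effects plus the two variance
    components; ties go to the smaller model.
    """
    y = np.asarray(trait_values, float)
    n = y.size
    km = KinshipModel(kinship.values)
    best: ModelSpec | None = None
    for name, C in sorted(
        candidate_covariate_sets.items(), key=lambda kv: 0 if kv[1] is None else np.atleast_2d(kv[1]).shape[-1]
    ):
        X = np.ones((n, 1))
        if C is not None and np.size(C):
            C2 = np.asarray(C, float)
            C2 = C2.reshape(n, -1)
            X = np.column_stack([X, C2])
        fit = km.fit(y, X)
        b = bic(fit["loglik"], X.shape[1] + 2, n)
        spec = ModelSpec(covariates=[] if C is None else [name], kinship=True, bic=float(b))
        if best is None or b < best.bic - 1e-12:
            best = spec
    return best


# ---------------------------------------------------------------------------
# Scans
# ---------------------------------------------------------------------------


def r2_likelihood(ll_full: float, ll_null: float, n: int) -> float:
    """Likelihood-ratio R^2 = 1 - exp(-(2/n)(LL_full - LL_null)), in [0, 1)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if ll_full < ll_null - 1e-9:
        raise ValueError("ll_full must be >= ll_null")
    return float(np.clip(1.0 - np.exp(-(2.0 / n) * (ll_full - ll_null)), 0.0, 1.0 - 1e-16))


def _scan(
    y: np.ndarray,
    features: np.ndarray,
    km: KinshipModel,
    X0: np.ndarray,
    exact: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Wald test of each feature column added to the null design X0.

    Returns (p, beta, r2_lr).  Constant features get p = 1, beta = 0.
    """
    n, m = features.shape
    null = km.fit(y, X0)
    yr, X0r = null["yr"], null["Xr"]
    Fr = km.rotate(features)
    p_out = np.ones(m)
    b_out = np.zeros(m)
    r2_out = np.zeros(m)
    const = features.std(axis=0) == 0
    dof = n - X0.shape[1] - 1
    for j in range(m):
        if const[j]:
            continue
        Xr = np.column_stack([X0r, Fr[:, j]])
        if exact:
            fit = km.fit(y, np.column_stack([X0, features[:, j]]))
            w = fit["weights"]
            ll_full = fit["loglik"]
            # null likelihood at the per-feature variance ratio
            ll_null = km._profile_ll(yr, X0r, fit["delta"])[0]
            beta, cov = fit["beta"], fit["beta_cov_unscaled"]
            sigma2 = fit["sigma_g2"] * n / dof
        else:
            w = null["weights"]
            Xw = Xr * w[:, None]
            A = Xr.T @ Xw
            cov = np.linalg.inv(A)
            beta = cov @ (Xw.T @ yr)
            r = yr - Xr @ beta
            rss = float(r @ (w * r))
            sigma2 = rss / dof
            ll_full = km._profile_ll(yr, Xr, null["delta"])[0]
            ll_null = null["loglik"]
        se = np.sqrt(sigma2 * cov[-1, -1])
        t = beta[-1] / se if se > 0 else 0.0
        p_out[j] = 2.0 * stats.t.sf(abs(t), df=dof)
        b_out[j] = beta[-1]
        r2_out[j] = r2_likelihood(max(ll_full, ll_null), ll_null, n)
    p_out = np.clip(p_out, np.finfo(float).tiny, 1.0)
    return p_out, b_out, r2_out


def _as_assoc_table(meta: pd.DataFrame, p, beta, r2, trait_id: str, method: str) -> pd.DataFrame:
    out = meta.copy()
    out["p"] = p
    out["effect"] = beta
    out["r2_lr"] = r2
    out["trait_id"] = trait_id
    out["method"] = method
    out["rank"] = out["p"].rank(method="first").astype(int)
    return out


def gwas_scan(
    trait_values: np.ndarray | pd.Series,
    genotypes: GenotypeMatrix,
    kinship: KinshipMatrix,
    covariates: np.ndarray | None = None,
    mode: str = "p3d",
    trait_id: str = "trait",
) -> pd.DataFrame:
    """Mixed-linear-model GWAS of a trait against every SNP.

    "p3d" estimates the variance components once on the null model and reuses
    them per SNP; "exact" re-optimizes the variance ratio for every SNP.
    Returns an association table with columns feature_id, chrom, pos, p,
    effect, r2_lr, rank.
    """
    y = np.asarray(trait_values, float)
    if y.size != genotypes.n_lines:
        raise ValueError("trait and genotype line sets are not aligned")
    X0 = np.ones((y.size, 1))
    if covariates is not None and np.size(covariates):
        X0 = np.column_stack([X0, np.asarray(covariates, float).reshape(y.size, -1)])
    km = KinshipModel(kinship.values)
    p, b, r2 = _scan(y, genotypes.dosages.astype(float), km, X0, exact=(mode == "exact"))
    meta = genotypes.snp_meta[["snp_id", "chrom", "pos"]].rename(columns={"snp_id": "feature_id"})
    return _as_assoc_table(meta.reset_index(drop=True), p, b, r2, trait_id, "GWAS")


def twas_scan(
    trait_values: np.ndarray | pd.Series,
    expression: pd.DataFrame,
    kinship: KinshipMatrix,
    covariates: np.ndarray | None = None,
    per_gene_reml: bool = True,
    trait_id: str = "trait",
) -> pd.DataFrame:
    """Mixed-model TWAS: test each gene's (residualized) expression as a covariate.

    ``per_gene_reml=True`` re-estimates the variance ratio for every gene.
    Genes with missing entries (outlier-screened lines) are tested on their
    complete lines only.
    """
    y = np.asarray(trait_values, float)
    n = y.size
    X0 = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        X0 = np.column_stack([X0, np.asarray(covariates, float).reshape(n, -1)])
    E = expression.to_numpy(float)
    km = KinshipModel(kinship.values)
    has_nan = np.isnan(E).any(axis=0)
    p = np.ones(E.shape[1])
    b = np.zeros(E.shape[1])
    r2 = np.zeros(E.shape[1])
    full = ~has_nan
    if full.any():
        p[full], b[full], r2[full] = _scan(y, E[:, full], km, X0, exact=per_gene_reml)
    for j in np.flatnonzero(has_nan):
        ok = ~np.isnan(E[:, j])
        if ok.sum() < X0.shape[1] + 3 or E[ok, j].std() == 0:
            continue
        K_sub = kinship.values[np.ix_(ok, ok)]
        km_sub = KinshipModel(K_sub)
        pj, bj, rj = _scan(y[ok], E[ok, j][:, None], km_sub, X0[ok], exact=per_gene_reml)
        p[j], b[j], r2[j] = pj[0], bj[0], rj[0]
    meta = pd.DataFrame({"feature_id": list(expression.columns)})
    return _as_assoc_table(meta, p, b, r2, trait_id, "TWAS")


def genomic_inflation(pvals: np.ndarray) -> float:
    """lambda_GC: median association chi2 over the null median (0.4549)."""
    chi2 = stats.chi2.isf(np.asarray(pvals, float), df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))
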