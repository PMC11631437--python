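"""REML variance-component estimation and EMMA-style kinship mixed models.

Two model families are implemented:

* :func:`fit_variance_components` — a general Gaussian mixed model with
  independent random effects, y = Xb + sum_k Z_k u_k + e with
  u_k ~ N(0, sigma2_k I).  Used for the multi-environment trait model
  (genotype, environment, GxE, block, column, instrument terms).  The REML
  log-likelihood is maximized over log-variances with analytic gradients.

* :class:`KinshipModel` — the single-random-effect model
  y = Xb + u + e, u ~ N(0, sigma2_g K), solved through the eigendecomposition
  of K so that the variance ratio delta = sigma2_e / sigma2_g can be profiled
  cheaply.  This is the engine behind the GWAS/TWAS scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, eigh

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class VarianceComponents:
    """Estimated variance components of a mixed model fit."""

    components: dict[str, float]  # term -> variance (includes "residual")
    loglik: float  # REML log-likelihood at the optimum
    converged: bool

    def __getitem__(self, term: str) -> float:
        return self.components[term]


@dataclass
class MixedModelFit:
    vc: VarianceComponents
    beta: np.ndarray
    blups: dict[str, np.ndarray]  # term -> BLUP vector (level order as Z columns)
    residuals: np.ndarray  # conditional residuals y - Xb - sum Z u


def _reml_nll_grad(theta, y, X, Gs, var_y):
    """Negative REML log-likelihood and gradient in theta = log sigma2."""
    n, p = X.shape
    sig = np.exp(theta)
    V = sig[-1] * np.eye(n)
    for s, G in zip(sig[:-1], Gs):
        V += s * G
    c, low = cho_factor(V, lower=True)
    logdetV = 2.0 * np.sum(np.log(np.diag(c)))
    Vinv = cho_solve((c, low), np.eye(n))
    XtVinv = X.T @ Vinv
    A = XtVinv @ X
    sign, logdetA = np.linalg.slogdet(A)
    Ainv = np.linalg.inv(A)
    P = Vinv - XtVinv.T @ Ainv @ XtVinv
    Py = P @ y
    nll = 0.5 * (logdetV + logdetA + y @ Py + (n - p) * _LOG2PI)
    grad = np.empty_like(sig)
    for k, G in enumerate(Gs):
        grad[k] = 0.5 * (np.sum(P * G) - Py @ G @ Py) * sig[k]
    grad[-1] = 0.5 * (np.trace(P) - Py @ Py) * sig[-1]
    return nll, grad


def fit_variance_components(
    y: np.ndarray,
    X: np.ndarray,
    Z_list: list[np.ndarray],
    names: list[str],
    max_iter: int = 200,
) -> MixedModelFit:
    """REML fit of a multi-component mixed model.

    Parameters are log-variances optimized with L-BFGS-B; a component whose
    estimate pins at the lower bound is effectively dropped (variance ~ 0).
    Non-convergence is flagged rather than raised: the components at the last
    iterate are returned with ``converged=False``.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n = y.size
    if X.shape[0] != n:
        raise ValueError("X and y have incompatible shapes")
    var_y = float(np.var(y))
    if var_y <= 0:
        raise ValueError("response has zero variance")
    Gs = [Z @ Z.T for Z in Z_list]
    k = len(Gs)
    theta0 = np.full(k + 1, np.log(var_y / (k + 1)))
    lb = np.log(var_y * 1e-10)
    ub = np.log(var_y * 1e4)
    res = optimize.minimize(
        _reml_nll_grad,
        theta0,
        args=(y, X, Gs, var_y),
        jac=True,
        method="L-BFGS-B",
        bounds=[(lb, ub)] * (k + 1),
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8},
    )
    sig = np.exp(res.x)
    # solve the mixed-model equations at the optimum: numerically stable even
    # when the residual variance is (near) zero, unlike inverting V directly
    W = np.column_stack([X] + Z_list)
    p = X.shape[1]
    lam = np.concatenate(
        [np.zeros(p)]
        + [np.full(Z.shape[1], sig[-1] / s) for s, Z in zip(sig[:-1], Z_list)]
    )
    # augmented least squares: minimize ||y - W theta||^2 + theta' D theta,
    # solved by SVD so the conditioning scales with sqrt of the MME's
    aug = np.vstack([W, np.diag(np.sqrt(lam))])
    rhs = np.concatenate([y, np.zeros(W.shape[1])])
    sol = np.linalg.lstsq(aug, rhs, rcond=None)[0]
    beta = sol[:p]
    blups = {}
    off = p
    for name, Z in zip(names, Z_list):
        blups[name] = sol[off : off + Z.shape[1]]
        off += Z.shape[1]
    resid = y - W @ sol
    comps = {name: float(s) for name, s in zip(names, sig[:-1])}
    comps["residual"] = float(sig[-1])
    vc = VarianceComponents(components=comps, loglik=float(-res.fun), converged=bool(res.success))
    return MixedModelFit(vc=vc, beta=beta, blups=blups, residuals=resid)


def blups_at_components(
    y: np.ndarray,
    X: np.ndarray,
    Z_list: list[np.ndarray],
    sigmas: list[float],
    sigma_resid: float,
) -> list[np.ndarray]:
    """BLUPs of each random term at fixed (not estimated) variance components.

    Useful for studying shrinkage behavior: u_k = sigma2_k Z_k' P y with P the
    projected inverse covariance at the supplied components.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n = y.size
    V = sigma_resid * np.eye(n)
    for s, Z in zip(sigmas, Z_list):
        V += s * (Z @ Z.T)
    c, low = cho_factor(V, lower=True)
    Vinv = cho_solve((c, low), np.eye(n))
    XtVinv = X.T @ Vinv
    beta = np.linalg.solve(XtVinv @ X, XtVinv @ y)
    Vinv_r = Vinv @ (y - X @ beta)
    return [s * (Z.T @ Vinv_r) for s, Z in zip(sigmas, Z_list)]


# ---------------------------------------------------------------------------
# Kinship (EMMA-style) model
# ---------------------------------------------------------------------------


class KinshipModel:
    """y = Xb + u + e with u ~ N(0, sigma2_g K), solved in K's eigenbasis.

    After rotation by the eigenvectors of K the covariance is diagonal,
    diag(sigma2_g * (lambda_i + delta)) with delta = sigma2_e / sigma2_g, so
    GLS fits at any delta are O(n p^2).  ``delta`` is profiled on a log grid
    refined by golden-section search; likelihoods are ML (used both for BIC
    model selection and for the likelihood-ratio R^2).
    """

    DELTA_GRID = np.logspace(-5, 5, 61)

    def __init__(self, K: np.ndarray):
        K = np.asarray(K, float)
        vals, vecs = eigh(K)
        neg = vals < -1e-8
        if neg.any():
            raise ValueError("kinship matrix is not positive semidefinite")
        self.eigvals = np.clip(vals, 0.0, None)
        self.U = vecs

    def rotate(self, M: np.ndarray) -> np.ndarray:
        return self.U.T @ M

    def _profile_ll(self, yr: np.ndarray, Xr: np.ndarray, delta: float) -> tuple[float, np.ndarray, float]:
        """ML log-likelihood profiled over beta and sigma2_g at fixed delta."""
        n = yr.size
        w = 1.0 / (self.eigvals + delta)
        Xw = Xr * w[:, None]
        A = Xr.T @ Xw
        try:
            beta = np.linalg.solve(A, Xw.T @ yr)
        except np.linalg.LinAlgError:  # collinear covariates: minimum-norm fit
            beta = np.linalg.lstsq(A, Xw.T @ yr, rcond=None)[0]
        r = yr - Xr @ beta
        rss = float(r @ (w * r))
        sigma_g2 = rss / n
        ll = -0.5 * (n * _LOG2PI + n * np.log(sigma_g2) + np.sum(np.log(self.eigvals + delta)) + n)
        return ll, beta, sigma_g2

    def fit(self, y: np.ndarray, X: np.ndarray, delta: float | None = None):
        """Fit by ML over delta (or at a fixed delta). Returns a result dict."""
        yr = self.rotate(np.asarray(y, float))
        Xr = self.rotate(np.atleast_2d(np.asarray(X, float)))
        if delta is None:
            lls = [self._profile_ll(yr, Xr, d)[0] for d in self.DELTA_GRID]
            i = int(np.argmax(lls))
            lo = self.DELTA_GRID[max(i - 1, 0)]
            hi = self.DELTA_GRID[min(i + 1, len(self.DELTA_GRID) - 1)]
            res = optimize.minimize_scalar(
                lambda ld: -self._profile_ll(yr, Xr, float(np.exp(ld)))[0],
                bounds=(np.log(lo), np.log(hi)),
                method="bounded",
                options={"xatol": 1e-13},
            )
            delta = float(np.exp(res.x))
        ll, beta, sigma_g2 = self._profile_ll(yr, Xr, delta)
        n = yr.size
        w = 1.0 / (self.eigvals + delta)
        A = np.linalg.pinv((Xr * w[:, None]).T @ Xr)
        return {
            "delta": delta,
            "beta": beta,
            "sigma_g2": sigma_g2,
            "sigma_e2": sigma_g2 * delta,
            "loglik": ll,
            "beta_cov_unscaled": A,  # multiply by sigma2 estimate for Wald tests
            "yr": yr,
            "Xr": Xr,
            "weights": w,
        }
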