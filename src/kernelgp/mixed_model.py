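"""Ridge regression, GBLUP and kernel-ridge (RKHS) mixed models.

The central model is

    Y = F beta + g + eps,   g ~ N(0, sigma2_g * K),   eps ~ N(0, sigma2_e * I)

with F a fixed-effect design (by default an intercept) and K a kernel Gram
matrix.  For the linear kernel K = X X' this is GBLUP, whose marker-effect
(primal) counterpart is RR-BLUP: beta_markers = X' alpha with the dual
variables alpha = (K + lambda I)^-1 (Y - F beta), lambda = sigma2_e /
sigma2_g.  For a nonlinear kernel the same machinery performs kernel ridge
regression (RKHS regression); the feature-space primal is then unavailable
(the Gaussian kernel's feature space is infinite-dimensional) but
predictions only need alpha.

Variance components are estimated by EM-REML.  The implementation
eigendecomposes K = Q D Q' once and rotates Y and F into the eigenbasis,
where the marginal covariance V = sigma2_g D + sigma2_e I is diagonal, so
each EM iteration costs O(n f^2).  The E-step takes conditional moments of
g and eps given the data under the restricted likelihood; the M-step
updates are the classical closed forms

    sigma2_g <- sigma2_g + sigma2_g^2 (y'PKPy - tr(PK)) / n
    sigma2_e <- sigma2_e + sigma2_e^2 (y'PPy  - tr(P))  / n

with P = V^-1 - V^-1 F (F'V^-1F)^-1 F'V^-1.  Each step increases the
restricted log-likelihood, which is recorded per iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .kernels import GenotypeMatrix, GramMatrix, KernelSpec, KernelError

__all__ = [
    "RidgeSolution",
    "MixedModelFit",
    "ridge_primal",
    "ridge_dual",
    "em_reml_fit",
    "blup_predict",
    "marker_effects_from_dual",
    "profile_reml_lambda",
    "MixedModelError",
    "ConvergenceWarning",
]


class MixedModelError(ValueError):
    """Singular system, invalid variance structure or bad dimensions."""


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class RidgeSolution:
    """Primal and/or dual ridge coefficients at a fixed penalty lambda."""

    lam: float
    beta: np.ndarray | None = None     # p marker effects (primal)
    alpha: np.ndarray | None = None    # n dual variables
    fitted: np.ndarray | None = None


@dataclass
class MixedModelFit:
    """Converged (or best-effort) kernel mixed-model solution.

    ``g_hat = K alpha_hat`` are the fitted genetic values; ``lambda_hat =
    sigma2_e / sigma2_g`` is the implied ridge penalty; ``reml_trace`` holds
    the restricted log-likelihood at each EM iteration (non-decreasing).
    """

    beta_fixed: np.ndarray
    alpha_hat: np.ndarray
    g_hat: np.ndarray
    sigma2_g: float
    sigma2_e: float
    lambda_hat: float
    reml_trace: np.ndarray
    converged: bool
    n_iter: int
    at_floor: bool = False
    spec: KernelSpec | None = None
    fitted: np.ndarray = field(default=None)  # F beta + g_hat

    def summary(self) -> dict:
        return {
            "sigma2_g": self.sigma2_g,
            "sigma2_e": self.sigma2_e,
            "lambda_hat": self.lambda_hat,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "at_floor": self.at_floor,
            "restricted_loglik": float(self.reml_trace[-1]),
        }


def _as_matrix(X) -> np.ndarray:
    return X.values if isinstance(X, (GenotypeMatrix, GramMatrix)) else np.asarray(X, dtype=float)


def ridge_primal(X, Y, lam: float) -> RidgeSolution:
    """Primal ridge estimate beta = (X'X + lambda I_p)^-1 X' Y.

    ``Y`` is assumed centered (or the intercept otherwise removed).  With
    lambda = 0 this is OLS and requires X'X to be invertible, which fails
    when p > n: with more markers than accessions the unpenalized fit is
    non-unique and interpolates the data (the overfitting regime that
    motivates regularization).
    """
    V = _as_matrix(X)
    y = np.asarray(Y, dtype=float)
    n, p = V.shape
    if y.shape != (n,):
        raise MixedModelError(f"phenotype length {y.shape} does not match n={n}")
    if lam < 0:
        raise MixedModelError("lambda must be non-negative")
    A = V.T @ V + lam * np.eye(p)
    try:
        c, low = scipy.linalg.cho_factor(A)
        beta = scipy.linalg.cho_solve((c, low), V.T @ y)
    except np.linalg.LinAlgError as exc:
        raise MixedModelError(
            f"X'X is singular at lambda=0 (n={n}, p={p}): with p >= n the "
            "unpenalized least-squares problem overfits and has no unique "
            "solution; use lambda > 0 or the dual formulation"
        ) from exc
    return RidgeSolution(lam=lam, beta=beta, fitted=V @ beta)


def ridge_dual(K, Y, lam: float) -> RidgeSolution:
    """Dual ridge / GBLUP: alpha = (K + lambda I_n)^-1 Y, fitted = K alpha.

    Identical fitted values to :func:`ridge_primal` when K = X X', but only
    an n x n system is solved — the usual route when p >> n.
    """
    M = _as_matrix(K)
    y = np.asarray(Y, dtype=float)
    n = M.shape[0]
    if M.shape != (n, n):
        raise MixedModelError("K must be square")
    if y.shape != (n,):
        raise MixedModelError(f"phenotype length {y.shape} does not match n={n}")
    if lam < 0:
        raise MixedModelError("lambda must be non-negative")
    try:
        if lam == 0:
            alpha = scipy.linalg.solve(M, y, assume_a="sym")
        else:
            c, low = scipy.linalg.cho_factor(M + lam * np.eye(n))
            alpha = scipy.linalg.cho_solve((c, low), y)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as exc:
        raise MixedModelError("K + lambda I is singular; increase lambda") from exc
    return RidgeSolution(lam=lam, alpha=alpha, fitted=M @ alpha)


def _reml_quantities(d, yt, Ft, s2g, s2e):
    """Pieces of the restricted likelihood in the eigenbasis of K."""
    v = s2g * d + s2e                      # diagonal of V
    Wv = Ft / v[:, None]                   # V^-1 F
    A = Ft.T @ Wv                          # F' V^-1 F
    cA, lowA = scipy.linalg.cho_factor(A)
    beta = scipy.linalg.cho_solve((cA, lowA), Wv.T @ yt)
    r = yt - Ft @ beta
    Py = r / v
    # trace terms: tr(P M) = sum(m/v) - tr(A^-1 F' V^-1 M V^-1 F) for diag M
    B = scipy.linalg.cho_solve((cA, lowA), Wv.T)   # A^-1 F' V^-1
    tr_P = (1.0 / v).sum() - np.einsum("fi,if->", B, Wv)
    Wd = Wv * d[:, None]
    tr_PK = (d / v).sum() - np.einsum("fi,if->", B, Wd)
    yPy = float(r @ Py)
    logdetA = 2.0 * np.log(np.diag(cA)).sum()
    loglik = -0.5 * (np.log(v).sum() + logdetA + yPy)
    return v, beta, Py, tr_P, tr_PK, yPy, loglik


def em_reml_fit(
    K,
    Y,
    F: np.ndarray | None = None,
    init: tuple[float, float] | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MixedModelFit:
    """EM-REML estimation of (sigma2_g, sigma2_e) for Y = F beta + g + eps.

    Parameters
    ----------
    K : GramMatrix or (n, n) array
        PSD kernel matrix; eigendecomposed once, zero eigenvalues retained
        (a singular K, e.g. linear kernel with p < n, needs no
        pseudo-inverse — the model only ever uses K + lambda I).
    Y : (n,) array
        Phenotypes; must not be constant.
    F : (n, f) array, optional
        Fixed-effect design, full column rank; defaults to an intercept.
    init : (sigma2_g, sigma2_e), optional
        Starting values.  Default splits var(Y) in half, with the genetic
        half expressed on the scale of K (divided by mean(diag K)) so the
        start is comparably sensible for unit-diagonal and raw X X' kernels.
    tol : float
        Convergence: absolute change in restricted log-likelihood.
    max_iter : int
        EM iteration cap; non-convergence returns the best fit with
        ``converged=False`` and a :class:`ConvergenceWarning` (EM is known
        to converge slowly when one component is small).
    """
    spec = K.spec if isinstance(K, GramMatrix) else None
    M = _as_matrix(K)
    y = np.asarray(Y, dtype=float)
    n = M.shape[0]
    if M.shape != (n, n):
        raise MixedModelError("K must be square")
    if y.shape != (n,):
        raise MixedModelError(f"phenotype length {y.shape} does not match n={n}")
    vary = float(np.var(y, ddof=1))
    if vary <= 0:
        raise MixedModelError("phenotypes have zero variance; nothing to fit")
    if F is None:
        F = np.ones((n, 1))
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or F.shape[0] != n:
        raise MixedModelError("fixed-effect design must be (n, f)")
    f = F.shape[1]
    if n <= f or np.linalg.matrix_rank(F) < f:
        raise MixedModelError("fixed-effect design must have full column rank with n > f")

    d, Q = scipy.linalg.eigh(M)
    scale = max(1.0, float(np.diag(M).max(initial=0.0)))
    if d[0] < -1e-8 * scale:
        raise MixedModelError(
            f"K is not positive semi-definite (min eigenvalue {d[0]:.3g})"
        )
    d = np.clip(d, 0.0, None)
    yt = Q.T @ y
    Ft = Q.T @ F

    mean_diag = float(np.diag(M).mean())
    if init is None:
        s2g = 0.5 * vary / max(mean_diag, np.finfo(float).tiny)
        s2e = 0.5 * vary
    else:
        s2g, s2e = float(init[0]), float(init[1])
        if s2g <= 0 or s2e <= 0:
            raise MixedModelError("initial variance components must be positive")

    floor = 1e-10 * vary
    floor_g = floor / max(mean_diag, np.finfo(float).tiny)
    trace = []
    converged = False
    at_floor = False
    it = 0
    for it in range(1, max_iter + 1):
        v, beta, Py, tr_P, tr_PK, yPy, loglik = _reml_quantities(d, yt, Ft, s2g, s2e)
        trace.append(loglik)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        s2g = s2g + s2g**2 * (float(Py @ (d * Py)) - tr_PK) / n
        s2e = s2e + s2e**2 * (float(Py @ Py) - tr_P) / n
        if s2g < floor_g:
            s2g, at_floor = floor_g, True
        if s2e < floor:
            s2e, at_floor = floor, True
    if not converged:
        warnings.warn(
            f"EM-REML did not converge in {max_iter} iterations "
            f"(last change {abs(trace[-1] - trace[-2]):.3g})",
            ConvergenceWarning,
        )

    v, beta, Py, *_ = _reml_quantities(d, yt, Ft, s2g, s2e)
    alpha = Q @ (s2g * Py)                 # BLUP of the dual variables
    g_hat = M @ alpha
    fitted = F @ beta + g_hat
    return MixedModelFit(
        beta_fixed=beta,
        alpha_hat=alpha,
        g_hat=g_hat,
        sigma2_g=float(s2g),
        sigma2_e=float(s2e),
        lambda_hat=float(s2e / s2g),
        reml_trace=np.asarray(trace),
        converged=converged,
        n_iter=it,
        at_floor=at_floor,
        spec=spec,
        fitted=fitted,
    )


def blup_predict(fit: MixedModelFit, K_cross: np.ndarray, F_new: np.ndarray | None = None) -> np.ndarray:
    """Predict responses for new accessions: F_new beta + K_cross alpha.

    ``K_cross`` must be computed against the training accessions with the
    training kernel spec and centering constants.  With the training Gram
    matrix itself this returns the in-sample fitted values.
    """
    Kc = np.asarray(K_cross, dtype=float)
    if Kc.ndim != 2 or Kc.shape[1] != fit.alpha_hat.shape[0]:
        raise MixedModelError(
            f"K_cross must have {fit.alpha_hat.shape[0]} columns (training accessions)"
        )
    m = Kc.shape[0]
    if F_new is None:
        F_new = np.ones((m, fit.beta_fixed.shape[0]))
        if fit.beta_fixed.shape[0] != 1:
            raise MixedModelError("F_new required when the fit has covariates")
    F_new = np.asarray(F_new, dtype=float)
    if F_new.shape != (m, fit.beta_fixed.shape[0]):
        raise MixedModelError("F_new shape does not match fixed-effect count")
    return F_new @ fit.beta_fixed + Kc @ fit.alpha_hat


def marker_effects_from_dual(X, alpha_hat: np.ndarray, spec: KernelSpec | None = None) -> np.ndarray:
    """RR-BLUP marker effects beta = X' alpha from a linear-kernel fit.

    Only the linear kernel admits this back-transformation: its feature map
    is the identity, so dual variables convert to one effect per marker and
    X beta reproduces K alpha exactly.  For a nonlinear kernel the effects
    live in the (possibly infinite-dimensional) feature space and no
    per-marker primal exists.
    """
    if spec is not None and spec.family != "linear":
        raise MixedModelError(
            f"marker effects are only defined for the linear kernel; a "
            f"{spec.family!r} kernel's primal coefficients live in feature "
            "space and cannot be mapped back to individual markers"
        )
    V = _as_matrix(X)
    a = np.asarray(alpha_hat, dtype=float)
    if a.shape != (V.shape[0],):
        raise MixedModelError("alpha length does not match accession count")
    return V.T @ a


def profile_reml_lambda(
    K,
    Y,
    F: np.ndarray | None = None,
    log10_grid: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Profile restricted log-likelihood over lambda = sigma2_e / sigma2_g.

    For each grid lambda, sigma2_g is profiled out in closed form
    (sigma2_g_hat = y' P_M y / (n - f) with M = K + lambda I), giving a 1-D
    criterion whose maximizer can be compared with the EM-REML estimate.
    Returns ``(best_lambda, lambdas, logliks)``.
    """
    M = _as_matrix(K)
    y = np.asarray(Y, dtype=float)
    n = M.shape[0]
    if F is None:
        F = np.ones((n, 1))
    F = np.asarray(F, dtype=float)
    f = F.shape[1]
    if log10_grid is None:
        log10_grid = np.arange(-4.0, 6.0 + 1e-12, 0.01)
    d, Q = scipy.linalg.eigh(M)
    d = np.clip(d, 0.0, None)
    yt = Q.T @ y
    Ft = Q.T @ F
    lams = 10.0 ** np.asarray(log10_grid, dtype=float)
    lls = np.empty_like(lams)
    for i, lam in enumerate(lams):
        m = d + lam
        Wv = Ft / m[:, None]
        A = Ft.T @ Wv
        cA, lowA = scipy.linalg.cho_factor(A)
        beta = scipy.linalg.cho_solve((cA, lowA), Wv.T @ yt)
        r = yt - Ft @ beta
        yPy = float(r @ (r / m))
        s2g = yPy / (n - f)
        logdetA = 2.0 * np.log(np.diag(cA)).sum()
        # restricted loglik at (s2g, lam), constants dropped
        lls[i] = -0.5 * (
            n * np.log(s2g) + np.log(m).sum()
            - f * np.log(s2g) + logdetA
            + yPy / s2g
        )
    best = int(np.argmax(lls))
    return float(lams[best]), lams, lls
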