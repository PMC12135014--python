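"""REML estimation of genotypic (C) and phenotypic (P) trait covariances.

The single-trait model is ``y = mu + g + e`` with ``g ~ N(0, G sigma_g^2)``
where G is the genomic relationship matrix, and ``e ~ N(0, I sigma_e^2)``.
Estimation is by restricted maximum likelihood: a single eigendecomposition
of G rotates the model into independent coordinates, after which the REML
objective is a one-dimensional function of the heritability that is
maximized numerically.

Multi-trait covariance matrices are assembled from univariate fits (the
diagonals) plus pairwise bivariate EM-REML fits (the off-diagonals), each
on the complete-case intersection of the trait pair.  This pairwise
strategy is far more robust than a joint t-trait REML when yearly samples
are small and traits go unmeasured in some years; an eigenvalue-bending
pass restores positive (semi)definiteness of the assembled matrices when
needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import optimize

from .index_core import CovarianceEstimate, ConditioningError
from .kernels import KernelMatrix

__all__ = [
    "UnivariateFit",
    "BivariateFit",
    "fit_univariate_greml",
    "fit_bivariate_greml",
    "assemble_covariances",
    "trait_summaries",
]

log = logging.getLogger(__name__)

_EIG_FLOOR = 1e-8


@dataclass
class UnivariateFit:
    sigma_g_sq: float
    sigma_e_sq: float
    h2: float
    loglik: float
    boundary: bool


@dataclass
class BivariateFit:
    C: np.ndarray  # 2x2 genetic covariance
    E_res: np.ndarray  # 2x2 residual covariance
    loglik: float
    n_iter: int
    converged: bool

    @property
    def P(self) -> np.ndarray:
        return self.C + self.E_res

    @property
    def genetic_correlation(self) -> float:
        return float(self.C[0, 1] / np.sqrt(self.C[0, 0] * self.C[1, 1]))


def _rotate(G: KernelMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    K = G.K if isinstance(G, KernelMatrix) else np.asarray(G, dtype=float)
    vals, vecs = np.linalg.eigh(K)
    if vals[0] < -1e-6 * max(vals[-1], 1e-300):
        raise ConditioningError("G is not positive semidefinite")
    return np.maximum(vals, 0.0), vecs


def _reml_loglik_1d(h2: float, lam: np.ndarray, zy: np.ndarray, zx: np.ndarray) -> float:
    """Restricted log-likelihood profiled over the total variance.

    Parametrized by h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2); the rotated
    weights are w_i = h2*lam_i + (1-h2).
    """
    w = h2 * lam + (1.0 - h2)
    if np.any(w <= 0):
        return -np.inf
    xtvx = float((zx * zx / w).sum())
    beta = float((zx * zy / w).sum()) / xtvx
    r = zy - zx * beta
    n, p = zy.size, 1
    rss = float((r * r / w).sum())
    sigma_tot = rss / (n - p)
    return -0.5 * (
        float(np.log(w).sum())
        + (n - p) * np.log(sigma_tot)
        + np.log(xtvx)
        + (n - p)
    )


def fit_univariate_greml(y: np.ndarray, G: KernelMatrix | np.ndarray) -> UnivariateFit:
    """Single-trait GREML via eigen-rotation and 1-D REML maximization.

    Returns variance components, heritability and the REML log-likelihood.
    Boundary estimates (h2 at 0 or 1) are flagged, not raised.
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("y must be complete for the fitted lines")
    lam, U = _rotate(G)
    zy = U.T @ y
    zx = U.T @ np.ones_like(y)
    res = optimize.minimize_scalar(
        lambda h2: -_reml_loglik_1d(h2, lam, zy, zx),
        bounds=(1e-6, 1.0 - 1e-6),
        method="bounded",
        options={"xatol": 1e-8},
    )
    h2 = float(res.x)
    ll = -float(res.fun)
    # recover total variance at the optimum
    w = h2 * lam + (1.0 - h2)
    xtvx = float((zx * zx / w).sum())
    beta = float((zx * zy / w).sum()) / xtvx
    r = zy - zx * beta
    sigma_tot = float((r * r / w).sum()) / (y.size - 1)
    boundary = h2 < 1e-4 or h2 > 1 - 1e-4
    if boundary:
        h2 = float(np.clip(h2, 0.0, 1.0))
    return UnivariateFit(
        sigma_g_sq=h2 * sigma_tot,
        sigma_e_sq=(1.0 - h2) * sigma_tot,
        h2=h2,
        loglik=ll,
        boundary=boundary,
    )


def _floor_2x2(M: np.ndarray, rel: float = 1e-9) -> np.ndarray:
    vals, vecs = np.linalg.eigh(M)
    floor = rel * max(np.trace(M), 1e-300)
    if vals[0] >= floor:
        return M
    return (vecs * np.maximum(vals, floor)) @ vecs.T


def _blocks(Sg: np.ndarray, Se: np.ndarray, lam: np.ndarray):
    """Per-observation 2x2 covariance blocks, inverses and log-dets."""
    V = lam[:, None, None] * Sg + Se  # (n, 2, 2)
    det = V[:, 0, 0] * V[:, 1, 1] - V[:, 0, 1] * V[:, 1, 0]
    if np.any(det <= 0) or np.any(np.diagonal(V, axis1=1, axis2=2) <= 0):
        return None, None
    Winv = np.empty_like(V)
    Winv[:, 0, 0] = V[:, 1, 1]
    Winv[:, 1, 1] = V[:, 0, 0]
    Winv[:, 0, 1] = -V[:, 0, 1]
    Winv[:, 1, 0] = -V[:, 1, 0]
    Winv /= det[:, None, None]
    return Winv, np.log(det)


def _bivariate_reml_loglik(
    Sg: np.ndarray, Se: np.ndarray, lam: np.ndarray, Z: np.ndarray, m: np.ndarray
) -> float:
    """Restricted loglik of the rotated bivariate model (2x2 blocks)."""
    Winv, logdet = _blocks(Sg, Se, lam)
    if Winv is None:
        return -np.inf
    XtVX = np.einsum("i,ijk->jk", m**2, Winv)
    XtVy = np.einsum("i,ijk,ik->j", m, Winv, Z)
    sign, ldx = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return -np.inf
    mu = np.linalg.solve(XtVX, XtVy)
    r = Z - np.outer(m, mu)
    quad = float(np.einsum("ij,ijk,ik->", r, Winv, r))
    return -0.5 * (float(logdet.sum()) + ldx + quad)


def fit_bivariate_greml(
    y1: np.ndarray,
    y2: np.ndarray,
    G: KernelMatrix | np.ndarray,
    max_iter: int = 500,
    tol_param: float = 1e-6,
    tol_loglik: float = 1e-8,
) -> BivariateFit:
    """Two-trait EM-REML with genomic covariance structure G (x) Sigma_g.

    After rotating by the eigenvectors of G the observations are
    independent 2-vectors ``z_i ~ N(m_i mu, lam_i Sigma_g + Sigma_e)``,
    so each EM iteration costs O(n) 2x2 operations.  The E-step uses the
    REML projection (fixed-effect uncertainty included), which guarantees
    a non-decreasing restricted log-likelihood.  Starting values split the
    phenotypic variance evenly between the components.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if y1.shape != y2.shape:
        raise ValueError("trait vectors must have the same length")
    if np.isnan(y1).any() or np.isnan(y2).any():
        raise ValueError("trait vectors must be complete (use complete cases)")
    if y1.size < 30:
        log.warning("bivariate GREML on only %d lines", y1.size)
    lam, U = _rotate(G)
    Z = np.column_stack([U.T @ y1, U.T @ y2])  # n x 2 rotated data
    m = U.T @ np.ones(y1.size)  # rotated intercept column
    n = y1.size
    Y = np.column_stack([y1, y2])
    Pv = np.cov(Y.T)
    Sg = 0.5 * Pv + 1e-8 * np.eye(2)
    Se = 0.5 * Pv + 1e-8 * np.eye(2)
    use_g = lam > _EIG_FLOOR * max(lam[-1], 1e-300)
    q = int(use_g.sum())
    ll_old = _bivariate_reml_loglik(Sg, Se, lam, Z, m)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        Winv, _ = _blocks(Sg, Se, lam)
        if Winv is None:
            raise ConditioningError("bivariate EM reached an indefinite iterate")
        XtVX = np.einsum("i,ijk->jk", m**2, Winv)
        XtVy = np.einsum("i,ijk,ik->j", m, Winv, Z)
        XtVX_inv = np.linalg.inv(XtVX)
        mu = XtVX_inv @ XtVy
        r = Z - np.outer(m, mu)
        Pr = np.einsum("ijk,ik->ij", Winv, r)
        # REML projection blocks: W_i - m_i^2 W_i (X'V^-1X)^-1 W_i
        Pii = Winv - m[:, None, None] ** 2 * np.einsum(
            "ijk,kl,ilm->ijm", Winv, XtVX_inv, Winv
        )
        u_hat = lam[:, None] * (Pr @ Sg)  # (n, 2)
        SgPiiSg = np.einsum("jk,ikl,lm->ijm", Sg, Pii, Sg)
        cov_u = lam[:, None, None] * Sg - lam[:, None, None] ** 2 * SgPiiSg
        Eu = np.einsum("ij,ik->ijk", u_hat, u_hat) + cov_u
        with np.errstate(divide="ignore", invalid="ignore"):
            Sg_new = np.einsum(
                "i,ijk->jk", np.where(use_g, 1.0 / np.maximum(lam, 1e-300), 0.0), Eu
            )
        e_hat = Pr @ Se
        SePiiSe = np.einsum("jk,ikl,lm->ijm", Se, Pii, Se)
        Se_new = np.einsum("ij,ik->ijk", e_hat, e_hat).sum(0) + (
            Se[None] - SePiiSe
        ).sum(0)
        Sg_new = 0.5 * (Sg_new + Sg_new.T) / max(q, 1)
        Se_new = 0.5 * (Se_new + Se_new.T) / n
        # tiny eigenvalue floor keeps degenerate inputs (e.g. duplicated
        # traits) from producing singular 2x2 blocks; inactive otherwise
        Sg_new = _floor_2x2(Sg_new)
        Se_new = _floor_2x2(Se_new)
        delta = max(
            np.abs(Sg_new - Sg).max() / max(np.abs(Sg).max(), 1e-12),
            np.abs(Se_new - Se).max() / max(np.abs(Se).max(), 1e-12),
        )
        Sg, Se = Sg_new, Se_new
        ll = _bivariate_reml_loglik(Sg, Se, lam, Z, m)
        if delta < tol_param and abs(ll - ll_old) < tol_loglik:
            converged = True
            ll_old = ll
            break
        ll_old = ll
    if not converged:
        log.warning("bivariate EM-REML did not converge in %d iterations", max_iter)
    return BivariateFit(C=Sg, E_res=Se, loglik=ll_old, n_iter=n_iter, converged=converged)


def assemble_covariances(
    traits: list[str],
    univariate: dict[str, UnivariateFit],
    bivariate: dict[tuple[str, str], BivariateFit],
    n_lines: int = 0,
    year: str | None = None,
) -> CovarianceEstimate:
    """Assemble P and C from univariate diagonals and bivariate off-diagonals.

    All trait pairs must be fitted.  Bending to PSD/PD happens inside
    :class:`CovarianceEstimate` (with a warning) if the patchwork
    assembly is indefinite.
    """
    t = len(traits)
    if set(univariate) != set(traits):
        raise ValueError("univariate fits must cover exactly the trait set")
    need = set(frozenset(p) for p in combinations(traits, 2))
    have = set(frozenset(p) for p in bivariate)
    if need != have:
        raise ValueError("bivariate fits must cover exactly all trait pairs")
    C = np.zeros((t, t))
    E = np.zeros((t, t))
    for j, tr in enumerate(traits):
        C[j, j] = univariate[tr].sigma_g_sq
        E[j, j] = univariate[tr].sigma_e_sq
    for (a, b), fit in bivariate.items():
        ja, jb = traits.index(a), traits.index(b)
        C[ja, jb] = C[jb, ja] = fit.C[0, 1]
        E[ja, jb] = E[jb, ja] = fit.E_res[0, 1]
    return CovarianceEstimate(traits=list(traits), P=C + E, C=C, n_lines=n_lines, year=year)


def fit_year_covariances(
    pheno: "pd.DataFrame",
    traits: list[str],
    G: KernelMatrix,
    year: str | None = None,
    min_pair_n: int = 30,
) -> CovarianceEstimate:
    """Fit all univariate + pairwise GREML models for one year's table.

    ``pheno`` has a ``line_id`` column plus trait columns (NaN = missing);
    every fit subsets G to the complete-case lines involved.
    """
    import pandas as pd  # local import keeps module import light

    uni: dict[str, UnivariateFit] = {}
    for tr in traits:
        sub = pheno.dropna(subset=[tr])
        Gs = G.align(sub["line_id"].tolist())
        uni[tr] = fit_univariate_greml(sub[tr].to_numpy(), Gs)
    biv: dict[tuple[str, str], BivariateFit] = {}
    for a, b in combinations(traits, 2):
        sub = pheno.dropna(subset=[a, b])
        if len(sub) < min_pair_n:
            raise ValueError(
                f"only {len(sub)} complete cases for pair ({a}, {b}); need {min_pair_n}"
            )
        Gs = G.align(sub["line_id"].tolist())
        biv[(a, b)] = fit_bivariate_greml(sub[a].to_numpy(), sub[b].to_numpy(), Gs)
    return assemble_covariances(traits, uni, biv, n_lines=len(pheno), year=year)


def trait_summaries(fit: CovarianceEstimate) -> dict:
    """Heritabilities plus phenotypic and genotypic correlation matrices."""
    h2 = np.diag(fit.C) / np.diag(fit.P)
    def _corr(M: np.ndarray) -> np.ndarray:
        sd = np.sqrt(np.diag(M))
        with np.errstate(divide="ignore", invalid="ignore"):
            R = M / np.outer(sd, sd)
        R[~np.isfinite(R)] = np.nan
        return R
    return {
        "traits": list(fit.traits),
        "h2": h2,
        "phenotypic_correlation": _corr(fit.P),
        "genotypic_correlation": _corr(fit.C),
    }
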