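"""Linear phenotypic selection indices and their parameters.

A selection index ``I = b'(y - mu)`` ranks candidates on a linear
combination of observed trait values so as to predict the net genetic
merit ``H = w'c`` (a weighted sum of unobservable breeding values).
Three classical choices of ``b`` are implemented:

* the Smith index, ``b = P^{-1} C w``, which maximizes the correlation
  between I and H for known economic weights ``w``;
* the eigen index, whose coefficient vector is the leading eigenvector
  of the multi-trait heritability matrix ``P^{-1} C`` (no economic
  weights required; a diagonal transforming matrix F can re-sign or
  re-proportion the coefficients without changing the eigenvalue);
* the desired-gains index, ``b = P^{-1} C (C P^{-1} C)^{-1} d``, the
  minimum-variance index whose expected per-trait gains are proportional
  to breeder-imposed targets ``d``.

``P`` is the phenotypic and ``C`` the genotypic covariance matrix of the
traits; both are usually REML estimates (see :mod:`selindex.varcomp`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import linalg, stats

__all__ = [
    "CovarianceEstimate",
    "IndexWeights",
    "IndexResult",
    "ConditioningError",
    "selection_intensity",
    "smith_coefficients",
    "esim_coefficients",
    "dg_coefficients",
    "index_parameters",
    "index_values",
    "truncate_select",
]

Method = Literal["SIM", "ESIM", "DG"]

#: Trait-weight presets used throughout the rice study.
WEIGHT_PRESETS: dict[str, list[float]] = {
    "unit": [-1.0, 1.0, 1.0, 1.0],
    "economic": [-10.0, 10.0, 10.0, 70.0],
}

# condition number beyond which a solve is refused
_COND_MAX = 1e10
# relative eigenvalue floor used when bending an indefinite estimate
_BEND_FLOOR = 1e-6


class ConditioningError(np.linalg.LinAlgError):
    """A covariance matrix is too ill-conditioned (or not PD/PSD) to use."""


def _check_square_symmetric(M: np.ndarray, name: str, n: int) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.shape != (n, n):
        raise ValueError(f"{name} must be {n}x{n}, got {M.shape}")
    if not np.allclose(M, M.T, atol=1e-8 * max(1.0, np.abs(M).max())):
        raise ValueError(f"{name} must be symmetric")
    return 0.5 * (M + M.T)


def bend(M: np.ndarray, floor_rel: float = _BEND_FLOOR) -> tuple[np.ndarray, bool]:
    """Eigenvalue bending: floor eigenvalues at ``floor_rel * max(eig)``.

    Returns the (possibly) repaired matrix and a flag saying whether any
    eigenvalue was actually raised.  Small-sample REML estimates routinely
    violate positive (semi)definiteness; bending is the standard repair.
    """
    vals, vecs = np.linalg.eigh(M)
    top = vals[-1]
    if top <= 0:
        raise ConditioningError("matrix has no positive eigenvalue; cannot bend")
    floor = floor_rel * top
    if vals[0] >= floor:
        return M, False
    bent = (vecs * np.maximum(vals, floor)) @ vecs.T
    return 0.5 * (bent + bent.T), True


@dataclass
class CovarianceEstimate:
    """Phenotypic (P) and genotypic (C) trait covariance matrices.

    When both phenotype and marker data enter the REML fit, the genomic
    covariance matrix coincides with C, so a single matrix serves both
    roles here.
    """

    traits: list[str]
    P: np.ndarray
    C: np.ndarray
    n_lines: int = 0
    year: str | None = None

    def __post_init__(self) -> None:
        t = len(self.traits)
        self.P = _check_square_symmetric(self.P, "P", t)
        self.C = _check_square_symmetric(self.C, "C", t)
        P, bent_p = bend(self.P)
        C, bent_c = bend(self.C)
        if bent_p or bent_c:
            warnings.warn(
                f"covariance estimate for year={self.year!r} required eigenvalue "
                f"bending (P: {bent_p}, C: {bent_c})",
                stacklevel=2,
            )
        self.P, self.C = P, C

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def heritabilities(self) -> np.ndarray:
        """Broad-sense heritabilities C_jj / P_jj (raw; flagged if outside [0,1])."""
        h2 = np.diag(self.C) / np.diag(self.P)
        if np.any((h2 < 0) | (h2 > 1)):
            warnings.warn(
                f"heritabilities outside [0, 1] for year={self.year!r}: {h2}",
                stacklevel=2,
            )
        return h2

    def subset(self, traits: Sequence[str]) -> "CovarianceEstimate":
        """Restrict P and C to the given (measured) traits, preserving order."""
        idx = [self.traits.index(t) for t in traits]
        return CovarianceEstimate(
            traits=list(traits),
            P=self.P[np.ix_(idx, idx)],
            C=self.C[np.ix_(idx, idx)],
            n_lines=self.n_lines,
            year=self.year,
        )


@dataclass
class IndexWeights:
    """Weight specification for one index method.

    Exactly one of ``w`` (SIM economic weights), ``F_diag`` (ESIM
    transforming-matrix diagonal) or ``d`` (desired gains) must be set,
    matching ``method``.
    """

    method: Method
    traits: list[str]
    w: np.ndarray | None = None
    F_diag: np.ndarray | None = None
    d: np.ndarray | None = None

    def __post_init__(self) -> None:
        fields = {"SIM": "w", "ESIM": "F_diag", "DG": "d"}
        if self.method not in fields:
            raise ValueError(f"unknown method {self.method!r}")
        for name in ("w", "F_diag", "d"):
            val = getattr(self, name)
            if name == fields[self.method]:
                if val is None:
                    raise ValueError(f"{self.method} requires {name}")
                val = np.asarray(val, dtype=float)
                if val.shape != (len(self.traits),):
                    raise ValueError(
                        f"{name} must have length {len(self.traits)}, got {val.shape}"
                    )
                if name == "F_diag" and np.any(val == 0):
                    raise ValueError("F_diag entries must be nonzero")
                setattr(self, name, val)
            elif val is not None:
                raise ValueError(f"{name} must not be set for method {self.method}")

    @property
    def vector(self) -> np.ndarray:
        return {"SIM": self.w, "ESIM": self.F_diag, "DG": self.d}[self.method]

    def subset(self, traits: Sequence[str]) -> "IndexWeights":
        idx = [self.traits.index(t) for t in traits]
        kw = {"SIM": "w", "ESIM": "F_diag", "DG": "d"}[self.method]
        return IndexWeights(
            method=self.method, traits=list(traits), **{kw: self.vector[idx]}
        )


@dataclass
class IndexResult:
    """Fitted index coefficients and derived selection parameters."""

    method: Method
    traits: list[str]
    b: np.ndarray
    sigma_I: float
    response: float
    expected_gain: np.ndarray
    k: float
    correlation: float | None = None  # absent for DG
    lambda_sq: float | None = None  # ESIM leading eigenvalue
    w_E: np.ndarray | None = None  # ESIM implied weights C^-1 P beta

    def to_json(self) -> str:
        rec = {
            "method": self.method,
            "traits": self.traits,
            "b": list(np.round(self.b, 10)),
            "sigma_I": self.sigma_I,
            "R": self.response,
            "rho": self.correlation,
            "E": list(np.round(self.expected_gain, 10)),
            "lambda_sq": self.lambda_sq,
            "w_E": None if self.w_E is None else list(np.round(self.w_E, 10)),
            "k": self.k,
        }
        return json.dumps(rec)


def selection_intensity(p: float) -> float:
    """Truncation-selection intensity k = phi(z)/p at selected proportion p.

    ``z`` is the upper-p quantile of the standard normal; k is the mean
    standardized superiority of the selected fraction of an infinite
    normal population (k = 1.755 at p = 0.10).
    """
    if not 0 < p <= 1:
        raise ValueError(f"selected proportion must be in (0, 1], got {p}")
    if p == 1.0:
        return 0.0
    z = stats.norm.ppf(1.0 - p)
    return float(stats.norm.pdf(z) / p)


def _solve_spd(M: np.ndarray, rhs: np.ndarray, name: str) -> np.ndarray:
    """Solve M x = rhs via Cholesky, refusing ill-conditioned systems."""
    if np.linalg.cond(M) > _COND_MAX:
        raise ConditioningError(f"matrix {name} is ill-conditioned (cond > {_COND_MAX:g})")
    try:
        cf = linalg.cho_factor(M, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - bent upstream
        raise ConditioningError(f"matrix {name} is not positive definite") from exc
    return linalg.cho_solve(cf, rhs)


def smith_coefficients(cov: CovarianceEstimate, w: np.ndarray) -> np.ndarray:
    """Smith index coefficients: solve P b = C w."""
    w = np.asarray(w, dtype=float)
    if w.shape != (cov.n_traits,):
        raise ValueError(f"w must have length {cov.n_traits}")
    return _solve_spd(cov.P, cov.C @ w, "P")


def esim_coefficients(
    cov: CovarianceEstimate, F_diag: np.ndarray
) -> tuple[np.ndarray, float, np.ndarray]:
    """Eigen-index coefficients from the leading eigenpair of P^{-1}C.

    The eigenproblem ``P^{-1} C b = lambda b`` is solved in its symmetric
    generalized form ``C b = lambda P b`` (real eigenpairs guaranteed for
    symmetric C and PD P).  The leading eigenvector is scaled so its
    maximum-magnitude element equals +1, then the transforming matrix
    ``F = diag(F_diag)`` is applied: ``beta = F b_E``.  The eigenvalue is
    invariant to any valid F (similar matrices).

    Returns ``(beta, lambda_sq, w_E)`` with ``w_E = C^{-1} P beta`` the
    implied trait weights.
    """
    F_diag = np.asarray(F_diag, dtype=float)
    if F_diag.shape != (cov.n_traits,):
        raise ValueError(f"F_diag must have length {cov.n_traits}")
    if np.any(F_diag == 0):
        raise ValueError("F_diag entries must be nonzero")
    if np.linalg.cond(cov.P) > _COND_MAX:
        raise ConditioningError("matrix P is ill-conditioned")
    vals, vecs = linalg.eigh(cov.C, cov.P)
    lead = int(np.argmax(vals))
    lam = float(vals[lead])
    b_E = vecs[:, lead]
    # sign/scale convention: maximum-magnitude element becomes +1
    b_E = b_E / b_E[int(np.argmax(np.abs(b_E)))]
    beta = F_diag * b_E
    # eigen-residual check in the P^{-1}C form
    resid = np.linalg.norm(_solve_spd(cov.P, cov.C @ b_E, "P") - lam * b_E)
    if resid > 1e-8 * np.linalg.norm(b_E):
        raise ConditioningError(f"eigenpair residual {resid:.2e} exceeds tolerance")
    w_E = _solve_spd(cov.C, cov.P @ beta, "C")
    return beta, lam, w_E


def dg_coefficients(cov: CovarianceEstimate, d: np.ndarray) -> np.ndarray:
    """Desired-gains coefficients b = P^{-1} C (C P^{-1} C)^{-1} d.

    Among all b with C b = d this is the one of minimum index variance
    b'Pb (Lagrange solution of min sigma_I s.t. C b = d).
    """
    d = np.asarray(d, dtype=float)
    if d.shape != (cov.n_traits,):
        raise ValueError(f"d must have length {cov.n_traits}")
    CPinvC = cov.C @ _solve_spd(cov.P, cov.C, "P")
    CPinvC = 0.5 * (CPinvC + CPinvC.T)
    if np.linalg.cond(CPinvC) > _COND_MAX:
        raise ConditioningError("C is rank deficient: constraint C b = d infeasible")
    inner = _solve_spd(CPinvC, d, "CP^-1C")
    b_dg = _solve_spd(cov.P, cov.C @ inner, "P")
    resid = np.linalg.norm(cov.C @ b_dg - d)
    if resid > 1e-8 * max(1.0, np.linalg.norm(d)):
        raise ConditioningError(f"constraint residual {resid:.2e}: C b = d infeasible")
    return b_dg


def index_parameters(
    cov: CovarianceEstimate, spec: IndexWeights, b: np.ndarray, k: float
) -> IndexResult:
    """Selection response, correlation with H, and expected per-trait gain.

    For SIM/ESIM: R = k * sigma_I (valid because sigma_IH = sigma_I^2 at
    the optimal b), rho_HI = sqrt(b'Pb / w'Cw) with the ESIM using its
    implied weights w_E, and E = k C b / sigma_I.  For DG the covariance
    with H is undefined, so no correlation is reported and E = k d / sigma_I.
    """
    if k < 0:
        raise ValueError("selection intensity k must be >= 0")
    b = np.asarray(b, dtype=float)
    var_I = float(b @ cov.P @ b)
    if var_I <= 0:
        raise ConditioningError("index variance b'Pb is not positive")
    sigma_I = float(np.sqrt(var_I))
    lambda_sq: float | None = None
    w_E: np.ndarray | None = None
    correlation: float | None = None
    if spec.method == "SIM":
        weights = spec.w
    elif spec.method == "ESIM":
        _, lambda_sq, w_E = esim_coefficients(cov, spec.F_diag)
        weights = w_E
    else:
        weights = None
    if weights is not None:
        var_H = float(weights @ cov.C @ weights)
        if var_H <= 0:
            raise ConditioningError("net-genetic-merit variance w'Cw is not positive")
        correlation = float(abs(np.sqrt(var_I / var_H)))
    if spec.method == "DG":
        gain = k * spec.d / sigma_I
    else:
        gain = k * (cov.C @ b) / sigma_I
    return IndexResult(
        method=spec.method,
        traits=list(cov.traits),
        b=b,
        sigma_I=sigma_I,
        response=k * sigma_I,
        expected_gain=gain,
        k=k,
        correlation=correlation,
        lambda_sq=lambda_sq,
        w_E=w_E,
    )


def index_values(
    b: np.ndarray,
    phenotypes: np.ndarray,
    mu: np.ndarray | None = None,
) -> np.ndarray:
    """Per-line index values I_i = b'(y_i - mu).

    ``phenotypes`` is lines x traits, columns aligned with ``b``.  When
    ``mu`` is omitted the column means of the complete cases are used, so
    mean(I) over complete cases is 0.  Lines with any missing trait get a
    NaN index (no silent imputation).
    """
    b = np.asarray(b, dtype=float)
    Y = np.asarray(phenotypes, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != b.size:
        raise ValueError(f"phenotypes must be n x {b.size}")
    complete = ~np.isnan(Y).any(axis=1)
    if mu is None:
        if not complete.any():
            raise ValueError("no complete-case lines to compute trait means")
        mu = Y[complete].mean(axis=0)
    mu = np.asarray(mu, dtype=float)
    I = np.full(Y.shape[0], np.nan)
    I[complete] = (Y[complete] - mu) @ b
    return I


def truncate_select(I: np.ndarray, p: float, line_ids: Sequence | None = None) -> list:
    """Indices (or ids) of the ceil(p*n) lines with the largest index value.

    Ties are broken deterministically by line id (ascending).  Missing
    index values are never selected.
    """
    I = np.asarray(I, dtype=float)
    if I.size == 0:
        raise ValueError("empty index vector")
    if not 0 < p <= 1:
        raise ValueError(f"selected proportion must be in (0, 1], got {p}")
    ids = list(line_ids) if line_ids is not None else list(range(I.size))
    if len(ids) != I.size:
        raise ValueError("line_ids length mismatch")
    n_sel = int(np.ceil(p * I.size))
    order = sorted(
        (i for i in range(I.size) if not np.isnan(I[i])),
        key=lambda i: (-I[i], ids[i]),
    )
    return [ids[i] for i in order[:n_sel]]
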