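"""Genomic relationship matrix and environmental-covariate kernels.

Markers are biallelic SNP dosages (0/1/2 copies of allele A).  Coding
subtracts twice the allele frequency, giving 2-2p, 1-2p and -2p for
AA, Aa and aa; the genomic relationship matrix is then G = XX'/pi with
pi = sum 2 p q (F2 population) or sum 4 p q (doubled haploids).

Year-level environmental covariates (weather summaries, spectral bands,
...) enter prediction through kernels over years: a linear kernel
K = SS'/N on centered/standardized covariates, or a Gaussian kernel
exp(-d^2/h) with the median-heuristic bandwidth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "MarkerMatrix",
    "KernelMatrix",
    "ECTable",
    "code_markers",
    "genomic_relationship",
    "ec_linear_kernel",
    "ec_gaussian_kernel",
    "expand_year_kernel",
]

log = logging.getLogger(__name__)

PopulationType = Literal["F2", "DH"]
KernelKind = Literal["genomic_G", "ec_linear", "ec_gaussian", "expanded"]

_PSD_TOL = 1e-8


@dataclass
class MarkerMatrix:
    """Raw dosage matrix (lines x markers) with per-marker allele frequencies."""

    line_ids: list
    raw_dosages: np.ndarray
    marker_ids: list | None = None
    allele_freq: np.ndarray | None = None
    population_type: PopulationType = "F2"

    def __post_init__(self) -> None:
        D = np.asarray(self.raw_dosages, dtype=float)
        if D.ndim != 2 or D.shape[0] != len(self.line_ids):
            raise ValueError("raw_dosages must be n_lines x n_markers")
        ok = np.isnan(D) | np.isin(D, (0.0, 1.0, 2.0))
        if not ok.all():
            i, q = np.argwhere(~ok)[0]
            raise ValueError(
                f"dosage not in {{0,1,2}} or missing at line {self.line_ids[i]!r}, "
                f"marker column {q}: {D[i, q]!r}"
            )
        self.raw_dosages = D
        if self.marker_ids is None:
            self.marker_ids = [f"m{q}" for q in range(D.shape[1])]
        if self.allele_freq is not None:
            self.allele_freq = np.asarray(self.allele_freq, dtype=float)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return self.raw_dosages.shape[1]


@dataclass
class KernelMatrix:
    """Symmetric PSD similarity matrix over labelled entities (lines or years)."""

    labels: list
    K: np.ndarray
    kind: KernelKind

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=float)
        n = len(self.labels)
        if K.shape != (n, n):
            raise ValueError(f"K must be {n}x{n}")
        if not np.allclose(K, K.T, atol=1e-8 * max(1.0, np.abs(K).max())):
            raise ValueError("K must be symmetric")
        K = 0.5 * (K + K.T)
        vals = np.linalg.eigvalsh(K)
        if vals[0] < -_PSD_TOL * max(vals[-1], 1e-300):
            raise ValueError(
                f"K is not PSD: min eigenvalue {vals[0]:.3e} vs max {vals[-1]:.3e}"
            )
        self.K = K

    def align(self, labels: Sequence) -> np.ndarray:
        """Submatrix of K for the given labels (in that order)."""
        pos = {l: i for i, l in enumerate(self.labels)}
        try:
            idx = [pos[l] for l in labels]
        except KeyError as exc:
            raise KeyError(f"label {exc.args[0]!r} not in kernel") from None
        return self.K[np.ix_(idx, idx)]


@dataclass
class ECTable:
    """Year-level environmental covariates (years x covariates)."""

    years: list
    covariates: np.ndarray
    covariate_names: list | None = None

    def __post_init__(self) -> None:
        M = np.asarray(self.covariates, dtype=float)
        if M.ndim != 2 or M.shape[0] != len(self.years):
            raise ValueError("covariates must be n_years x n_covariates")
        if np.isnan(M).all(axis=0).any():
            raise ValueError("all-missing covariate column")
        self.covariates = M
        if self.covariate_names is None:
            self.covariate_names = [f"ec{j}" for j in range(M.shape[1])]


def code_markers(raw: MarkerMatrix) -> tuple[np.ndarray, np.ndarray, list]:
    """Center dosages to X = dosage - 2p, dropping monomorphic markers.

    Missing dosages are mean-imputed per marker before centering (count
    logged).  Returns ``(X, p, kept_marker_ids)``; column means of X are
    zero when p is the sample frequency.
    """
    D = raw.raw_dosages.copy()
    n_missing = int(np.isnan(D).sum())
    if n_missing:
        log.info("mean-imputing %d missing dosages", n_missing)
        col_mean = np.nanmean(D, axis=0)
        ii = np.where(np.isnan(D))
        D[ii] = col_mean[ii[1]]
    if raw.allele_freq is not None:
        p = raw.allele_freq
    else:
        p = D.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    n_drop = int((~poly).sum())
    if n_drop:
        log.info("dropping %d monomorphic markers", n_drop)
    X = D[:, poly] - 2.0 * p[poly]
    kept = [raw.marker_ids[q] for q in np.where(poly)[0]]
    return X, p[poly], kept


def genomic_relationship(
    X: np.ndarray,
    p: np.ndarray,
    line_ids: Sequence,
    population_type: PopulationType = "F2",
) -> KernelMatrix:
    """Genomic relationship matrix G = XX'/pi.

    pi = sum 2 p(1-p) over markers for an F2 population and twice that
    for doubled haploids.
    """
    X = np.asarray(X, dtype=float)
    p = np.asarray(p, dtype=float)
    het = 2.0 * p * (1.0 - p)
    pi = float(het.sum()) * (2.0 if population_type == "DH" else 1.0)
    if pi <= 0:
        raise ValueError("no polymorphic markers: pi = 0")
    G = X @ X.T / pi
    return KernelMatrix(labels=list(line_ids), K=G, kind="genomic_G")


def _standardize_columns(
    M: np.ndarray, names: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Center/scale columns to unit variance; drop constants (logged)."""
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    keep = sd > 0
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("dropping %d constant EC columns", n_drop)
    if not keep.any():
        raise ValueError("all covariates constant across years")
    S = (M[:, keep] - mean[keep]) / sd[keep]
    return S, mean[keep], sd[keep], [names[j] for j in np.where(keep)[0]]


def ec_linear_kernel(ec: ECTable) -> KernelMatrix:
    """Linear year kernel K = SS'/N on standardized covariates.

    Columns are centered and scaled to unit population (ddof=0) variance,
    so each has sum of squares n_years and trace(K) = n_years exactly;
    N is the number of retained covariates.  Constant columns are dropped
    with a logged count.
    """
    if len(ec.years) < 2:
        raise ValueError("at least 2 years required for an EC kernel")
    M = ec.covariates
    sd = M.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all covariates constant across years")
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("dropping %d constant EC columns", n_drop)
    S = (M[:, keep] - M[:, keep].mean(axis=0)) / sd[keep]
    K = S @ S.T / S.shape[1]
    return KernelMatrix(labels=list(ec.years), K=K, kind="ec_linear")


def ec_gaussian_kernel(ec: ECTable, bandwidth: float | None = None) -> KernelMatrix:
    """Gaussian year kernel K_ij = exp(-d_ij^2 / h) on standardized covariates.

    ``h`` defaults to the median off-diagonal squared Euclidean distance
    (median heuristic); with exactly two distinct years the off-diagonal
    entry is exp(-1).
    """
    if len(ec.years) < 2:
        raise ValueError("at least 2 years required for an EC kernel")
    S, _, _, _ = _standardize_columns(ec.covariates, ec.covariate_names)
    sq = ((S[:, None, :] - S[None, :, :]) ** 2).sum(axis=2)
    off = sq[np.triu_indices_from(sq, k=1)]
    if bandwidth is None:
        h = float(np.median(off))
        if h <= 0:
            log.warning("all pairwise EC distances are zero; Gaussian kernel is all ones")
            return KernelMatrix(
                labels=list(ec.years), K=np.ones_like(sq), kind="ec_gaussian"
            )
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
    K = np.exp(-sq / h)
    return KernelMatrix(labels=list(ec.years), K=K, kind="ec_gaussian")


def expand_year_kernel(
    K_year: KernelMatrix, year_of_line: Mapping
) -> KernelMatrix:
    """Expand a year x year kernel to lines: K_lines = Z K Z' (PSD preserved)."""
    pos = {y: i for i, y in enumerate(K_year.labels)}
    lines = list(year_of_line.keys())
    try:
        idx = np.array([pos[year_of_line[l]] for l in lines])
    except KeyError as exc:
        raise KeyError(f"year {exc.args[0]!r} not present in year kernel") from None
    K = K_year.K[np.ix_(idx, idx)]
    return KernelMatrix(labels=lines, K=K, kind="expanded")
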