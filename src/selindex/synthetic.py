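"""Synthetic marker / phenotype / environmental-covariate generator.

Emulates the statistical structure of a multi-year rice breeding trial:
~435 biallelic SNPs, four quality/yield traits with year-specific
missingness, 134-348 mostly-new lines per year, broad-sense
heritabilities around 0.4-0.6, and year-level environmental covariates.

Genetic values are produced through per-marker effects (g = X u, with u
drawn MVN across traits and scaled by the marker heterozygosity sum pi),
so the GREML model used downstream is correctly specified and prediction
across years through the genomic relationship matrix is meaningful.
Trait units are not policed (no % bounds); all downstream analysis is
covariance-level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .index_core import CovarianceEstimate
from .kernels import ECTable, MarkerMatrix

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "simulate_markers",
    "simulate_phenotypes",
    "simulate_ec",
    "simulate_dataset",
    "worked_example_fixture",
]

TRAITS = ["Chalk", "Whole", "Ratoon", "Yield"]

#: genetic variances / correlations sized so heritabilities land near the
#: multi-year averages 0.46 / 0.58 / 0.44 / 0.54
_DEFAULT_C = np.array(
    [
        [2.93, 0.60, 0.04, 0.15],
        [0.60, 11.60, 0.16, 0.62],
        [0.04, 0.16, 0.22, 0.04],
        [0.15, 0.62, 0.04, 0.36],
    ]
)
_DEFAULT_H2 = np.array([0.46, 0.58, 0.44, 0.54])


def _default_residual() -> np.ndarray:
    g = np.diag(_DEFAULT_C)
    e = g * (1.0 - _DEFAULT_H2) / _DEFAULT_H2
    R = np.diag(e).astype(float)
    # mild residual correlation
    for j in range(4):
        for h in range(j + 1, 4):
            R[j, h] = R[h, j] = 0.05 * np.sqrt(e[j] * e[h])
    return R


#: which traits were measured each year (others missing for the whole year)
DEFAULT_MISSING_PATTERN = {
    2018: ("Chalk", "Whole", "Ratoon", "Yield"),
    2019: ("Chalk", "Whole", "Yield"),
    2020: ("Chalk", "Yield"),
    2021: ("Chalk", "Ratoon", "Yield"),
    2022: ("Chalk", "Whole", "Ratoon", "Yield"),
}

DEFAULT_N_PER_YEAR = {2018: 134, 2019: 332, 2020: 307, 2021: 348, 2022: 300}


@dataclass
class SyntheticConfig:
    """All generator knobs; a single seed drives every draw."""

    n_per_year: dict = field(default_factory=lambda: dict(DEFAULT_N_PER_YEAR))
    m_markers: int = 435
    traits: list[str] = field(default_factory=lambda: list(TRAITS))
    target_C: np.ndarray = field(default_factory=lambda: _DEFAULT_C.copy())
    target_residual: np.ndarray = field(default_factory=_default_residual)
    missing_pattern: dict = field(
        default_factory=lambda: dict(DEFAULT_MISSING_PATTERN)
    )
    n_ec: int = 20
    year_effects: dict | None = None  # year -> per-trait shift vector
    family_size: int = 5  # relatedness blocks within a year
    n_checks: int = 3  # lines shared across consecutive years
    sigma_yc_sq: float = 0.0  # variance of an injected year-level EC effect
    seed: int = 0

    def __post_init__(self) -> None:
        t = len(self.traits)
        self.target_C = np.asarray(self.target_C, dtype=float)
        self.target_residual = np.asarray(self.target_residual, dtype=float)
        for name, M in (("target_C", self.target_C), ("target_residual", self.target_residual)):
            if M.shape != (t, t):
                raise ValueError(f"{name} must be {t}x{t}")
            if np.linalg.eigvalsh(M)[0] < -1e-8:
                raise ValueError(f"{name} must be positive semidefinite")
        for yr, measured in self.missing_pattern.items():
            if len(measured) < 2:
                raise ValueError(f"year {yr} must measure at least 2 traits")
        if self.m_markers < 2:
            raise ValueError("need at least 2 markers")


@dataclass
class SyntheticDataset:
    """Markers, phenotypes, ECs and the generating truth, for one seed."""

    config: SyntheticConfig
    markers: MarkerMatrix
    phenotypes: pd.DataFrame  # line_id, year, trait columns (NaN = unmeasured)
    genetic_values: pd.DataFrame  # same layout, no missingness
    ec: ECTable
    year_of_line: dict


def simulate_markers(cfg: SyntheticConfig) -> tuple[MarkerMatrix, dict]:
    """Dosage matrix for all years' lines with family relatedness blocks.

    Allele frequencies ~ U(0.05, 0.95).  Lines come in families of
    ``family_size``: members copy each founder allele with probability
    1/2 and draw fresh otherwise, giving G useful off-diagonal structure.
    Consecutive years share ``n_checks`` lines (the study's few repeated
    checks); all other line sets are disjoint across years.
    """
    rng = np.random.default_rng(cfg.seed)
    p = rng.uniform(0.05, 0.95, size=cfg.m_markers)
    years = sorted(cfg.n_per_year)
    line_ids: list[str] = []
    year_of_line: dict = {}
    rows: list[np.ndarray] = []

    def draw_family_block(k: int) -> np.ndarray:
        founder = rng.binomial(2, p, size=cfg.m_markers).astype(float)
        block = np.empty((k, cfg.m_markers))
        for i in range(k):
            fresh = rng.binomial(2, p, size=cfg.m_markers).astype(float)
            copy = rng.random(cfg.m_markers) < 0.5
            block[i] = np.where(copy, founder, fresh)
        return block

    prev_checks: list[tuple[str, np.ndarray]] = []
    for yr in years:
        n = cfg.n_per_year[yr]
        carried = prev_checks[: cfg.n_checks] if prev_checks else []
        for lid, dos in carried:
            line_ids.append(lid)
            year_of_line.setdefault(lid, yr)  # keep first year for G labels
            rows.append(dos)
        n_new = n - len(carried)
        new_ids = [f"L{yr}_{i:04d}" for i in range(n_new)]
        made = 0
        blocks = []
        while made < n_new:
            k = min(max(cfg.family_size, 1), n_new - made)
            blocks.append(draw_family_block(k))
            made += k
        new_dos = np.vstack(blocks)
        for lid, dos in zip(new_ids, new_dos):
            line_ids.append(lid)
            year_of_line[lid] = yr
            rows.append(dos)
        prev_checks = list(zip(new_ids[: cfg.n_checks], new_dos[: cfg.n_checks]))

    # check lines appear once in the marker matrix (unique line ids)
    seen: set = set()
    uniq_ids, uniq_rows = [], []
    for lid, dos in zip(line_ids, rows):
        if lid not in seen:
            seen.add(lid)
            uniq_ids.append(lid)
            uniq_rows.append(dos)
    markers = MarkerMatrix(
        line_ids=uniq_ids,
        raw_dosages=np.vstack(uniq_rows),
        population_type="F2",
    )
    # membership: every (line, year) pair actually grown
    year_members: dict = {}
    ptr = 0
    for yr in years:
        n = cfg.n_per_year[yr]
        year_members[yr] = line_ids[ptr : ptr + n]
        ptr += n
    return markers, year_members


def simulate_ec(cfg: SyntheticConfig, rng: np.random.Generator | None = None) -> ECTable:
    """Year x covariate table from a low-rank latent year factor plus noise."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    years = sorted(cfg.n_per_year)
    if len(years) < 2:
        raise ValueError("need at least 2 years")
    z = rng.normal(size=(len(years), 2))  # latent year conditions
    load = rng.normal(size=(2, cfg.n_ec))
    M = z @ load + 0.3 * rng.normal(size=(len(years), cfg.n_ec))
    return ECTable(years=list(years), covariates=M)


def simulate_phenotypes(
    cfg: SyntheticConfig,
    markers: MarkerMatrix,
    year_members: dict,
    ec: ECTable | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trait phenotypes via marker effects: Y = year shift + X u + residual.

    Per-marker effect vectors across traits are MVN(0, target_C / pi), so
    the genetic covariance of line values is target_C in expectation.
    Residuals are MVN(0, target_residual).  Optionally a year-level EC
    effect with variance sigma_yc_sq (structured by the linear EC kernel)
    is added.  The year's unmeasured traits are set to NaN in the
    phenotype table; the returned genetic-value table is complete.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    t = len(cfg.traits)
    D = markers.raw_dosages
    p = D.mean(axis=0) / 2.0
    X = D - 2.0 * p
    pi = float((2.0 * p * (1.0 - p)).sum())
    if pi <= 0:
        raise ValueError("monomorphic marker panel")
    # marker effects: m x t, rows iid MVN(0, target_C / pi)
    Lc = np.linalg.cholesky(cfg.target_C + 1e-10 * np.eye(t))
    U = rng.normal(size=(markers.n_markers, t)) @ Lc.T / np.sqrt(pi)
    Gvals = X @ U  # n_lines x t true genetic values
    gv = pd.DataFrame(Gvals, columns=cfg.traits)
    gv.insert(0, "line_id", markers.line_ids)
    pos = {l: i for i, l in enumerate(markers.line_ids)}

    years = sorted(year_members)
    shifts = cfg.year_effects or {}
    ec_effect = {yr: np.zeros(t) for yr in years}
    if cfg.sigma_yc_sq > 0:
        if ec is None:
            raise ValueError("EC table required to inject an EC effect")
        from .kernels import ec_linear_kernel

        Ky = ec_linear_kernel(ec).align(years)
        Lk = np.linalg.cholesky(Ky + 1e-8 * np.eye(len(years)))
        draw = Lk @ rng.normal(size=(len(years), t)) * np.sqrt(cfg.sigma_yc_sq)
        ec_effect = {yr: draw[i] for i, yr in enumerate(years)}

    Le = np.linalg.cholesky(cfg.target_residual + 1e-10 * np.eye(t))
    rec_p, rec_g = [], []
    for yr in years:
        measured = set(cfg.missing_pattern.get(yr, cfg.traits))
        shift = np.asarray(shifts.get(yr, np.zeros(t)), dtype=float)
        for lid in year_members[yr]:
            g = Gvals[pos[lid]]
            eps = Le @ rng.normal(size=t)
            y = shift + g + eps + ec_effect[yr]
            row = {"line_id": lid, "year": yr}
            grow = {"line_id": lid, "year": yr}
            for j, tr in enumerate(cfg.traits):
                row[tr] = y[j] if tr in measured else np.nan
                grow[tr] = g[j]
            rec_p.append(row)
            rec_g.append(grow)
    return pd.DataFrame(rec_p), pd.DataFrame(rec_g)


def simulate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """End-to-end generation: markers, ECs, phenotypes, truth."""
    markers, year_members = simulate_markers(cfg)
    ec = simulate_ec(cfg)
    pheno, gvals = simulate_phenotypes(cfg, markers, year_members, ec=ec)
    year_of_line = {}
    for yr, lids in year_members.items():
        for lid in lids:
            year_of_line.setdefault(lid, yr)
    return SyntheticDataset(
        config=cfg,
        markers=markers,
        phenotypes=pheno,
        genetic_values=gvals,
        ec=ec,
        year_of_line=year_of_line,
    )


def worked_example_fixture() -> CovarianceEstimate:
    """The 2020 Chalk/Yield covariance estimates used as a worked example."""
    return CovarianceEstimate(
        traits=["Chalk", "Yield"],
        P=np.array([[6.67, 0.54], [0.54, 0.71]]),
        C=np.array([[2.93, 0.31], [0.31, 0.36]]),
        n_lines=307,
        year="2020",
    )
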