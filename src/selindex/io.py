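"""Readers and writers for the pipeline's plain-text formats.

Phenotypes: TSV with ``line_id``, ``year``, then trait columns ("NA" =
missing).  Markers: CSV dosage matrix (lines x markers, values 0/1/2) or
a VCF of biallelic SNPs.  ECs: CSV with a ``year`` column.  Results: TSV
ranked by correlation plus a JSON summary.  Readers reject malformed
input rather than coercing it, and every dropped record is logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .kernels import ECTable, KernelMatrix, MarkerMatrix

__all__ = [
    "RunConfig",
    "load_run_config",
    "read_phenotypes",
    "read_markers",
    "read_markers_vcf",
    "read_ec",
    "write_kernel",
    "read_kernel",
    "write_report",
]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated run configuration (flat YAML key/value file).

    Every field can be overridden by the matching CLI flag; unknown keys
    in the file are rejected rather than ignored.
    """

    phenotypes: str | None = None
    markers: str | None = None
    ec: str | None = None
    weights: str = "unit"
    method: str = "SIM"
    proportion: float = 0.10
    population_type: str = "F2"
    target_year: int | None = None
    out_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.proportion <= 1:
            raise ValueError(f"proportion must be in (0, 1], got {self.proportion}")
        if self.population_type not in ("F2", "DH"):
            raise ValueError(f"unknown population_type {self.population_type!r}")
        if self.method not in ("SIM", "ESIM", "DG"):
            raise ValueError(f"unknown method {self.method!r}")
        for name in ("phenotypes", "markers", "ec"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")


def load_run_config(path: str | Path) -> RunConfig:
    """Flat YAML config -> RunConfig; unknown keys are an error."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a flat mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Phenotype TSV -> typed DataFrame; duplicate (line, year) is an error."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"line_id": str})
    required = {"line_id", "year"}
    if not required <= set(df.columns):
        raise ValueError(f"phenotype file must have columns {sorted(required)}")
    dup = df.duplicated(subset=["line_id", "year"], keep=False)
    if dup.any():
        pair = df.loc[dup, ["line_id", "year"]].iloc[0].tolist()
        raise ValueError(f"duplicate (line, year) pair: {tuple(pair)}")
    traits = [c for c in df.columns if c not in required]
    for c in traits:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"trait column {c!r} is not numeric: {exc}") from None
    return df


def read_markers(path: str | Path) -> MarkerMatrix:
    """CSV dosage matrix (first column line id) -> MarkerMatrix."""
    df = pd.read_csv(path, index_col=0)
    D = df.to_numpy(dtype=float)
    bad = ~(np.isnan(D) | np.isin(D, (0.0, 1.0, 2.0)))
    if bad.any():
        i, q = np.argwhere(bad)[0]
        raise ValueError(
            f"dosage not in {{0,1,2}} at line {df.index[i]!r}, marker {df.columns[q]!r}: "
            f"{D[i, q]!r}"
        )
    return MarkerMatrix(
        line_ids=[str(x) for x in df.index],
        raw_dosages=D,
        marker_ids=list(df.columns),
    )


def read_markers_vcf(path: str | Path) -> MarkerMatrix:
    """VCF of biallelic SNPs -> 0/1/2 dosages (multi-allelic records skipped)."""
    from cyvcf2 import VCF  # deferred: optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    ids: list[str] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        gts = rec.genotype.array()[:, :2]
        dose = np.where((gts < 0).any(axis=1), np.nan, gts.clip(min=0).sum(axis=1))
        cols.append(dose.astype(float))
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
    if n_skipped:
        log.info("skipped %d non-biallelic VCF records", n_skipped)
    if not cols:
        raise ValueError("no biallelic SNPs in VCF")
    return MarkerMatrix(
        line_ids=samples, raw_dosages=np.column_stack(cols), marker_ids=ids
    )


def write_markers(markers: MarkerMatrix, path: str | Path) -> None:
    pd.DataFrame(
        markers.raw_dosages, index=markers.line_ids, columns=markers.marker_ids
    ).to_csv(path)


def read_ec(path: str | Path) -> ECTable:
    """CSV with a ``year`` column plus numeric covariate columns."""
    df = pd.read_csv(path)
    if "year" not in df.columns:
        raise ValueError("EC file must have a 'year' column")
    years = df["year"].tolist()
    cov = df.drop(columns="year")
    return ECTable(
        years=years,
        covariates=cov.to_numpy(dtype=float),
        covariate_names=list(cov.columns),
    )


def write_ec(ec: ECTable, path: str | Path) -> None:
    df = pd.DataFrame(ec.covariates, columns=ec.covariate_names)
    df.insert(0, "year", ec.years)
    df.to_csv(path, index=False)


def write_kernel(kernel: KernelMatrix, path: str | Path) -> None:
    """Kernel -> labelled TSV; round-trips exactly via repr-precision floats."""
    df = pd.DataFrame(kernel.K, index=kernel.labels, columns=kernel.labels)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_kernel(path: str | Path, kind: str = "expanded") -> KernelMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return KernelMatrix(labels=list(df.index), K=df.to_numpy(dtype=float), kind=kind)


def write_report(results: list[dict], out_prefix: str | Path) -> tuple[Path, Path]:
    """Per-task correlations -> ranked TSV + JSON summary.

    ``results`` rows carry index method, weights label, training years,
    EC policy, model and correlation.  The TSV is sorted by descending
    correlation (ties broken by sub-model id); an empty result list
    yields a header-only TSV and a warning.
    """
    out_prefix = Path(out_prefix)
    tsv = out_prefix.with_suffix(".tsv")
    js = out_prefix.with_suffix(".json")
    cols = ["index", "weights", "training_years", "ec_policy", "model", "submodel_id", "r"]
    if not results:
        log.warning("no results to report; writing header-only TSV")
        df = pd.DataFrame(columns=cols)
    else:
        df = pd.DataFrame(results)[cols]
        df = df.sort_values(
            ["r", "submodel_id"], ascending=[False, True], kind="mergesort"
        )
    df.to_csv(tsv, sep="\t", index=False)
    summary = {
        "n_tasks": int(len(df)),
        "mean_r": None if df.empty else float(df["r"].mean()),
        "max_r": None if df.empty else float(df["r"].max()),
        "min_r": None if df.empty else float(df["r"].min()),
    }
    js.write_text(json.dumps(summary, indent=2))
    return tsv, js
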