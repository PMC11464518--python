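"""Cohort readers/writers, first-day aggregation, missingness filtering.

File formats: cohort tables as CSV with a sidecar JSON echoing the
simulation or pipeline configuration; reference model sets as JSON;
networks as GraphML plus an edge-list TSV; survival reports as JSON with
per-table CSVs. Exact column names are documented in ``schema.json``
shipped alongside this module.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .parenclitic import ReferenceModelSet
from .synthetic import SimulationConfig

__all__ = [
    "PipelineConfig",
    "read_cohort",
    "write_cohort",
    "aggregate_first_24h",
    "missingness_filter",
    "write_graph",
    "read_graph",
    "write_models",
    "read_models",
    "write_report",
]

log = logging.getLogger("alfnet")


@dataclass(frozen=True)
class PipelineConfig:
    """Validated run configuration for the analysis pipeline."""

    variables: tuple[str, ...]
    alpha: float = 0.05
    deviation_convention: str = "standardized_residual"
    k: int = 3
    pca_variables: tuple[str, ...] = ()
    tie_method: str = "breslow"
    brier_method: str = "cox"
    seed: int = 0
    min_age: float = 18.0  # inclusion threshold; ambiguous in prose, config value

    def __post_init__(self) -> None:
        if not self.variables:
            raise ValueError("variables must be non-empty")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.deviation_convention not in (
            "standardized_residual",
            "raw_residual",
            "orthogonal",
        ):
            raise ValueError(f"unknown convention {self.deviation_convention!r}")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.tie_method not in ("breslow", "efron"):
            raise ValueError("tie_method must be 'breslow' or 'efron'")
        if self.brier_method not in ("cox", "logistic"):
            raise ValueError("brier_method must be 'cox' or 'logistic'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("variables", "pca_variables"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "alpha": self.alpha,
            "deviation_convention": self.deviation_convention,
            "k": self.k,
            "pca_variables": list(self.pca_variables),
            "tie_method": self.tie_method,
            "brier_method": self.brier_method,
            "seed": self.seed,
            "min_age": self.min_age,
        }


# ---------------------------------------------------------------------------
# cohort CSV round-trip


def write_cohort(
    cohort: pd.DataFrame,
    path: str | Path,
    config: SimulationConfig | None = None,
) -> None:
    """CSV with patient_id first; sidecar ``<path>.config.json`` when a
    simulation config is supplied (or stashed on the frame)."""
    path = Path(path)
    cols = list(cohort.columns)
    if "patient_id" in cols:
        cols.insert(0, cols.pop(cols.index("patient_id")))
    # default float formatting is the shortest round-trip repr; pair it with
    # float_precision="round_trip" on read for a lossless cycle
    cohort[cols].to_csv(path, index=False)
    cfg = config.to_dict() if config is not None else cohort.attrs.get(
        "simulation_config"
    )
    if cfg is not None:
        sidecar = path.with_suffix(path.suffix + ".config.json")
        sidecar.write_text(json.dumps(cfg, indent=2, sort_keys=True))


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV; reattaches the sidecar config when present."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    sidecar = path.with_suffix(path.suffix + ".config.json")
    if sidecar.exists():
        df.attrs["simulation_config"] = json.loads(sidecar.read_text())
    return df


# ---------------------------------------------------------------------------
# raw long-format events -> first-day means


def aggregate_first_24h(raw: pd.DataFrame) -> pd.DataFrame:
    """Mean of each variable over measurements in the [0, 24)-hour window.

    ``raw`` is long format with columns patient_id, variable, timestamp
    (hours since ICU admission), value. Patients with no first-day
    measurement at all are dropped and logged; malformed rows (negative or
    unparseable timestamps/values) are skipped and counted.
    """
    required = {"patient_id", "variable", "timestamp", "value"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"raw event table lacks columns: {sorted(missing)}")
    work = raw.copy()
    work["timestamp"] = pd.to_numeric(work["timestamp"], errors="coerce")
    work["value"] = pd.to_numeric(work["value"], errors="coerce")
    bad = work["timestamp"].isna() | work["value"].isna() | (work["timestamp"] < 0)
    if bad.any():
        log.warning("aggregate_first_24h: skipped %d malformed rows", int(bad.sum()))
    work = work[~bad]
    first_day = work[work["timestamp"] < 24.0]

    excluded = set(raw["patient_id"].unique()) - set(first_day["patient_id"].unique())
    for pid in sorted(map(str, excluded)):
        log.info(
            "excluded patient %s: no measurements within first 24 h", pid
        )
    wide = (
        first_day.groupby(["patient_id", "variable"])["value"]
        .mean()
        .unstack("variable")
        .reset_index()
    )
    wide.columns.name = None
    return wide


def missingness_filter(
    cohort: pd.DataFrame,
    variables: Sequence[str],
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Keep patients with at least ``min_fraction`` non-missing analysis
    variables (boundary inclusive); exclusions are logged with the rule."""
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must lie in (0, 1]")
    variables = [v for v in variables if v in cohort.columns]
    frac = cohort[variables].notna().mean(axis=1)
    keep = frac >= min_fraction
    for _, row in cohort[~keep].iterrows():
        pid = row.get("patient_id", "<unknown>")
        log.info(
            "excluded patient %s: %.0f%% non-missing < %.0f%% (missingness rule)",
            pid,
            100 * frac.loc[row.name],
            100 * min_fraction,
        )
    out = cohort[keep].reset_index(drop=True)
    if out.empty:
        raise ValueError("missingness filter removed every patient")
    return out


# ---------------------------------------------------------------------------
# graphs, models, reports


def write_graph(graph: nx.Graph, path: str | Path) -> None:
    """GraphML plus a ``.tsv`` edge list (source, target, weight)."""
    path = Path(path)
    nx.write_graphml(graph, path)
    tsv = path.with_suffix(".tsv")
    with open(tsv, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for u, v, d in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d.get('weight', 1.0):.17g}\n")


def read_graph(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


def write_models(models: ReferenceModelSet, path: str | Path) -> None:
    Path(path).write_text(models.to_json())


def read_models(path: str | Path) -> ReferenceModelSet:
    return ReferenceModelSet.from_json(Path(path).read_text())


def write_report(report, outdir: str | Path) -> None:
    """Survival report as JSON plus one CSV per result table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(
        json.dumps(report.to_json_dict(), indent=2, sort_keys=True, default=float)
    )
    report.group_comparisons.to_csv(outdir / "group_comparisons.csv", index=False)
    report.univariate_cox.to_csv(outdir / "univariate_cox.csv", index=False)
    report.multivariate_cox.to_csv(outdir / "multivariate_cox.csv", index=False)
    report.roc.to_csv(outdir / "roc.csv", index=False)
    report.improvement.to_csv(outdir / "improvement.csv", index=False)
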