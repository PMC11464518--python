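"""Parenclitic deviation mapping against a survivor reference population.

For every unordered pair of physiological variables, an ordinary
least-squares line is fitted in the reference population (28-day
survivors). Pairs whose Pearson correlation survives a Bonferroni
correction over all C(p, 2) comparisons define the significant axes. Each
patient's deviation delta-A/B from the reference line then quantifies the
loss of the expected physiological coupling; the deviations form the edge
weights of that patient's individual network map.

Deviation conventions
---------------------
standardized_residual
    |y - (a + b x)| / residual SD of the reference fit (scale-free, default).
raw_residual
    |y - (a + b x)| in the units of y.
orthogonal
    perpendicular distance to the line, computed on reference-z-scored
    coordinates (direction-free).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

__all__ = [
    "ReferenceModel",
    "ReferenceModelSet",
    "fit_reference_models",
    "compute_deviation",
    "deviation_matrix",
    "patient_network",
    "axis_label",
]

CONVENTIONS = ("standardized_residual", "raw_residual", "orthogonal")


def axis_label(var_x: str, var_y: str) -> str:
    """The delta-A/B axis name, A = regressor, B = response."""
    return f"δ-{var_x}/{var_y}"


@dataclass(frozen=True)
class ReferenceModel:
    """OLS fit of var_y on var_x in the reference population."""

    var_x: str
    var_y: str
    slope: float
    intercept: float
    residual_sd: float
    pearson_r: float
    p_value: float
    n_used: int
    significant: bool
    # reference means/SDs, needed by the orthogonal convention
    x_mean: float = float("nan")
    x_sd: float = float("nan")
    y_mean: float = float("nan")
    y_sd: float = float("nan")

    @property
    def label(self) -> str:
        return axis_label(self.var_x, self.var_y)


@dataclass(frozen=True)
class ReferenceModelSet:
    models: tuple[ReferenceModel, ...]
    alpha: float
    n_pairs_tested: int
    deviation_convention: str = "standardized_residual"

    def __post_init__(self) -> None:
        if self.deviation_convention not in CONVENTIONS:
            raise ValueError(
                f"unknown deviation convention {self.deviation_convention!r}"
            )

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.n_pairs_tested

    @property
    def significant_models(self) -> tuple[ReferenceModel, ...]:
        return tuple(m for m in self.models if m.significant)

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha": self.alpha,
                "n_pairs_tested": self.n_pairs_tested,
                "deviation_convention": self.deviation_convention,
                "models": [asdict(m) for m in self.models],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ReferenceModelSet":
        d = json.loads(text)
        return cls(
            models=tuple(ReferenceModel(**m) for m in d["models"]),
            alpha=d["alpha"],
            n_pairs_tested=d["n_pairs_tested"],
            deviation_convention=d["deviation_convention"],
        )


def _fit_pair(
    x: np.ndarray, y: np.ndarray, var_x: str, var_y: str, threshold: float
) -> ReferenceModel:
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        warnings.warn(
            f"pair ({var_x}, {var_y}): only {n} complete rows; model unfit",
            stacklevel=3,
        )
        return ReferenceModel(
            var_x, var_y, math.nan, math.nan, math.nan, math.nan, 1.0, n, False
        )
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        warnings.warn(
            f"pair ({var_x}, {var_y}): constant variable; model unfit",
            stacklevel=3,
        )
        return ReferenceModel(
            var_x, var_y, math.nan, math.nan, math.nan, math.nan, 1.0, n, False,
            float(xs.mean()), float(xs.std(ddof=1)),
            float(ys.mean()), float(ys.std(ddof=1)),
        )
    res = stats.linregress(xs, ys)
    resid = ys - (res.intercept + res.slope * xs)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    return ReferenceModel(
        var_x=var_x,
        var_y=var_y,
        slope=float(res.slope),
        intercept=float(res.intercept),
        residual_sd=residual_sd,
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n_used=n,
        significant=bool(res.pvalue < threshold),
        x_mean=float(xs.mean()),
        x_sd=float(xs.std(ddof=1)),
        y_mean=float(ys.mean()),
        y_sd=float(ys.std(ddof=1)),
    )


def fit_reference_models(
    reference: pd.DataFrame,
    variables: Sequence[str],
    alpha: float = 0.05,
    deviation_convention: str = "standardized_residual",
) -> ReferenceModelSet:
    """Fit one OLS model per unordered variable pair in the reference group.

    Pairwise-complete rows are used per pair. The significance flag applies
    a Bonferroni threshold of ``alpha / C(p, 2)`` to the two-tailed Pearson
    p-value; the denominator is fixed at C(p, 2) even when some pairs are
    unfit, which is conservative.
    """
    variables = sorted(variables)
    missing = [v for v in variables if v not in reference.columns]
    if missing:
        raise ValueError(f"reference table lacks variables: {missing}")
    n_pairs = math.comb(len(variables), 2)
    if n_pairs == 0:
        raise ValueError("need at least two variables")
    threshold = alpha / n_pairs
    cols = {v: reference[v].to_numpy(dtype=float) for v in variables}
    models = tuple(
        _fit_pair(cols[a], cols[b], a, b, threshold)
        for a, b in combinations(variables, 2)
    )
    return ReferenceModelSet(
        models=models,
        alpha=alpha,
        n_pairs_tested=n_pairs,
        deviation_convention=deviation_convention,
    )


def compute_deviation(
    model: ReferenceModel,
    x_p: float,
    y_p: float,
    convention: str = "standardized_residual",
) -> float:
    """Deviation of one patient from the reference line, always >= 0.

    NaN inputs propagate NaN.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown deviation convention {convention!r}")
    if not (math.isfinite(model.slope) and math.isfinite(model.intercept)):
        return math.nan
    if math.isnan(x_p) or math.isnan(y_p):
        return math.nan
    if convention == "orthogonal":
        # point-to-line distance on reference-z-scored coordinates; the
        # fitted line maps to slope*x_sd/y_sd through the scaled intercept
        zx = (x_p - model.x_mean) / model.x_sd
        zy = (y_p - model.y_mean) / model.y_sd
        b_z = model.slope * model.x_sd / model.y_sd
        c_z = (model.intercept + model.slope * model.x_mean - model.y_mean) / model.y_sd
        return abs(zy - b_z * zx - c_z) / math.sqrt(1.0 + b_z * b_z)
    raw = abs(y_p - (model.intercept + model.slope * x_p))
    if convention == "raw_residual":
        return raw
    if model.residual_sd == 0:
        raise ZeroDivisionError(
            "residual_sd is 0 (perfect reference fit); use the raw_residual "
            "convention for this axis"
        )
    return raw / model.residual_sd


def deviation_matrix(
    models: ReferenceModelSet,
    cohort: pd.DataFrame,
    convention: str | None = None,
) -> pd.DataFrame:
    """Per-patient deviations on every significant axis.

    Returns a DataFrame indexed like ``cohort`` (or by ``patient_id`` when
    present) with one delta-A/B column per significant model; missing inputs
    propagate NaN. ``.attrs['deviation_convention']`` records the convention.
    """
    convention = convention or models.deviation_convention
    sig = models.significant_models
    index = (
        pd.Index(cohort["patient_id"], name="patient_id")
        if "patient_id" in cohort.columns
        else cohort.index
    )
    out = {}
    for m in sig:
        if m.var_x not in cohort.columns or m.var_y not in cohort.columns:
            raise ValueError(f"cohort lacks variables for axis {m.label}")
        x = cohort[m.var_x].to_numpy(dtype=float)
        y = cohort[m.var_y].to_numpy(dtype=float)
        if convention == "orthogonal":
            zx = (x - m.x_mean) / m.x_sd
            zy = (y - m.y_mean) / m.y_sd
            b_z = m.slope * m.x_sd / m.y_sd
            c_z = (m.intercept + m.slope * m.x_mean - m.y_mean) / m.y_sd
            vals = np.abs(zy - b_z * zx - c_z) / math.sqrt(1 + b_z * b_z)
        else:
            raw = np.abs(y - (m.intercept + m.slope * x))
            if convention == "raw_residual":
                vals = raw
            else:
                if m.residual_sd == 0:
                    raise ZeroDivisionError(
                        f"axis {m.label}: residual_sd is 0; use raw_residual"
                    )
                vals = raw / m.residual_sd
        out[m.label] = vals
    dm = pd.DataFrame(out, index=index)
    dm.attrs["deviation_convention"] = convention
    return dm


def patient_network(
    deviations_row: pd.Series, threshold: float = 0.0
) -> nx.Graph:
    """Individual parenclitic network: nodes are variables, an edge carries
    weight delta-A/B whenever the deviation exceeds ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    g = nx.Graph()
    for label, value in deviations_row.items():
        name = str(label)
        if name.startswith("δ-"):
            name = name[len("δ-"):]
        a, _, b = name.partition("/")
        g.add_node(a)
        g.add_node(b)
        if np.isfinite(value) and value > threshold:
            g.add_edge(a, b, weight=float(value))
    return g
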