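"""Clinical severity scores: Glasgow Coma Score, King's College Criteria, SOFA.

KCC is computed as the *count* of criteria met (0-4): acidosis (arterial
pH < 7.30), coagulopathy (INR > 6.5), renal dysfunction (creatinine >
3.4 mg/dL), and deep hepatic encephalopathy, proxied by GCS <= 8 (West
Haven grade III/IV). Thresholds are strict inequalities.

SOFA is the Vincent 1996 banding, restricted to sub-scores computable from
first-day laboratory/vital variables: coagulation (platelets), liver
(bilirubin), cardiovascular (MAP only; vasopressor doses are out of scope),
CNS (GCS) and renal (creatinine). A respiration sub-score may be passed
through when a PaO2/FiO2-based value is available externally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GcsComponents",
    "KccInputs",
    "SofaInputs",
    "gcs_total",
    "kcc_score",
    "sofa_score",
    "add_scores",
]


@dataclass(frozen=True)
class GcsComponents:
    """Eye (1-4), verbal (1-5) and motor (1-6) responsiveness sub-scores."""

    eye: int
    verbal: int
    motor: int

    def __post_init__(self) -> None:
        for name, value, lo, hi in (
            ("eye", self.eye, 1, 4),
            ("verbal", self.verbal, 1, 5),
            ("motor", self.motor, 1, 6),
        ):
            if not (lo <= value <= hi):
                raise ValueError(
                    f"GCS component {name!r}={value} outside [{lo}, {hi}]"
                )


@dataclass(frozen=True)
class KccInputs:
    arterial_ph: float | None
    inr: float | None
    creatinine: float | None
    gcs_total: float | None

    def __post_init__(self) -> None:
        if self.arterial_ph is not None and not math.isnan(self.arterial_ph):
            if not (6.5 < self.arterial_ph < 8.0):
                raise ValueError(
                    f"arterial_ph={self.arterial_ph} outside plausible range (6.5, 8.0)"
                )
        for name in ("inr", "creatinine"):
            v = getattr(self, name)
            if v is not None and not math.isnan(v) and v <= 0:
                raise ValueError(f"{name}={v} must be positive")


@dataclass(frozen=True)
class SofaInputs:
    platelets: float | None
    bilirubin: float | None
    mean_arterial_pressure: float | None
    gcs_total: float | None
    creatinine: float | None
    respiration_score: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "platelets",
            "bilirubin",
            "mean_arterial_pressure",
            "gcs_total",
            "creatinine",
        ):
            v = getattr(self, name)
            if v is not None and not math.isnan(v) and v < 0:
                raise ValueError(f"{name}={v} must be non-negative")
        if self.respiration_score is not None and not (
            0 <= self.respiration_score <= 4
        ):
            raise ValueError("respiration_score must lie in [0, 4]")


def gcs_total(components: GcsComponents) -> int:
    """Total Glasgow Coma Score: eye + verbal + motor, range [3, 15]."""
    return components.eye + components.verbal + components.motor


def _is_missing(value: float | None) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def kcc_score(inputs: KccInputs, *, missing_policy: str = "unmet") -> int:
    """Count of King's College criteria met (0-4), strict thresholds.

    Criteria: arterial pH < 7.30; INR > 6.5; creatinine > 3.4 mg/dL;
    GCS <= 8 (West Haven grade III/IV proxy). A missing input counts the
    criterion as unmet with a warning under the default policy; with
    ``missing_policy='error'`` it raises.
    """
    if missing_policy not in ("unmet", "error"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    criteria = [
        ("arterial_ph", inputs.arterial_ph, lambda v: v < 7.30),
        ("inr", inputs.inr, lambda v: v > 6.5),
        ("creatinine", inputs.creatinine, lambda v: v > 3.4),
        ("gcs_total", inputs.gcs_total, lambda v: v <= 8),
    ]
    score = 0
    for name, value, rule in criteria:
        if _is_missing(value):
            if missing_policy == "error":
                raise ValueError(f"KCC input {name!r} is missing")
            warnings.warn(
                f"KCC input {name!r} missing; criterion counted as unmet",
                stacklevel=2,
            )
            continue
        if rule(value):
            score += 1
    return score


def _band(value: float, cutpoints: list[float]) -> int:
    """Sub-score from descending cutpoints: value < cutpoints[i] scores i+1."""
    score = 0
    for i, cut in enumerate(cutpoints):
        if value < cut:
            score = i + 1
    return score


def _sofa_coagulation(platelets: float) -> int:
    return _band(platelets, [150, 100, 50, 20])


def _sofa_liver(bilirubin: float) -> int:
    # bilirubin bands (mg/dL): >=1.2 / >=2.0 / >=6.0 / >=12.0
    score = 0
    for i, cut in enumerate([1.2, 2.0, 6.0, 12.0]):
        if bilirubin >= cut:
            score = i + 1
    return score


def _sofa_cardio(mean_arterial_pressure: float) -> int:
    return 1 if mean_arterial_pressure < 70 else 0


def _sofa_cns(gcs: float) -> int:
    if gcs >= 15:
        return 0
    if gcs >= 13:
        return 1
    if gcs >= 10:
        return 2
    if gcs >= 6:
        return 3
    return 4


def _sofa_renal(creatinine: float) -> int:
    score = 0
    for i, cut in enumerate([1.2, 2.0, 3.5, 5.0]):
        if creatinine >= cut:
            score = i + 1
    return score


def sofa_score(inputs: SofaInputs) -> int:
    """SOFA total from the computable sub-scores; missing inputs contribute 0."""
    total = 0
    if not _is_missing(inputs.platelets):
        total += _sofa_coagulation(inputs.platelets)
    if not _is_missing(inputs.bilirubin):
        total += _sofa_liver(inputs.bilirubin)
    if not _is_missing(inputs.mean_arterial_pressure):
        total += _sofa_cardio(inputs.mean_arterial_pressure)
    if not _is_missing(inputs.gcs_total):
        total += _sofa_cns(inputs.gcs_total)
    if not _is_missing(inputs.creatinine):
        total += _sofa_renal(inputs.creatinine)
    if inputs.respiration_score is not None:
        total += inputs.respiration_score
    return total


def add_scores(
    cohort: pd.DataFrame,
    *,
    gcs_col: str = "gcs",
    overwrite: bool = False,
) -> pd.DataFrame:
    """Batch-compute ``kcc`` and ``sofa`` columns over a cohort table.

    Expects columns ``ph``, ``inr``, ``creatinine``, ``platelets``,
    ``bilirubin``, ``map`` and the GCS column. Returns a copy with the two
    integer score columns appended.
    """
    out = cohort.copy()
    for col in ("kcc", "sofa"):
        if col in out.columns and not overwrite:
            raise ValueError(f"column {col!r} already present; pass overwrite=True")

    def _get(row: pd.Series, col: str) -> float:
        v = row.get(col, np.nan)
        return float(v) if pd.notna(v) else float("nan")

    kcc_vals, sofa_vals = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-row missing-input warnings
        for _, row in out.iterrows():
            kcc_vals.append(
                kcc_score(
                    KccInputs(
                        arterial_ph=_get(row, "ph"),
                        inr=_get(row, "inr"),
                        creatinine=_get(row, "creatinine"),
                        gcs_total=_get(row, gcs_col),
                    )
                )
            )
            sofa_vals.append(
                sofa_score(
                    SofaInputs(
                        platelets=_get(row, "platelets"),
                        bilirubin=_get(row, "bilirubin"),
                        mean_arterial_pressure=_get(row, "map"),
                        gcs_total=_get(row, gcs_col),
                        creatinine=_get(row, "creatinine"),
                    )
                )
            )
    out["kcc"] = np.asarray(kcc_vals, dtype=int)
    out["sofa"] = np.asarray(sofa_vals, dtype=int)
    return out
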