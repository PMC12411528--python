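"""Airway structural metrics from quantitative CT cross-section measurements.

For each labeled airway branch the upstream segmentation reports the luminal
cross-sectional area LA (mm^2), luminal perimeter Pe (mm), outer diameter
D_outer (mm) and average luminal diameter D_ave (mm).  Two scalars summarize
the branch geometry:

* hydraulic luminal diameter  Dh = 4 LA / Pe  (mm), and
* wall thickness              WT = (D_outer - D_ave) / 2  (mm).

Both are normalized by predicted healthy-reference values for the trachea,
obtained from regression equations in age, height and sex.  The published
transcriptions of those equations are not dimensionally interpretable as
printed (unbalanced logarithms, a unit-less height^2 x sex term), so the
term structure and coefficients live in an editable configuration
(:class:`PredictionEquation`) and the literal printed forms are shipped as
defaults; corrected equations can be dropped in without code changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AIRWAY_BRANCHES",
    "SUBGROUP_LABELS",
    "AirwayCrossSection",
    "SubjectCovariates",
    "PredictionEquation",
    "hydraulic_diameter",
    "wall_thickness",
    "predicted_trachea_dh",
    "predicted_trachea_wt",
    "normalize_metric",
    "compute_airway_metrics",
]

#: Named central branches.
AIRWAY_BRANCHES = (
    "Trachea", "LMB", "RMB", "Bronint",
    "TriRUL", "TriLUL", "TriRLL", "TriLLB",
)
#: Sub-lobar segmental groups.
SUBGROUP_LABELS = ("sRUL", "sRML", "sRLL", "sLUL", "sLLL")

_VALID_FACTORS = frozenset({"log_age", "log_height", "height2", "sex"})


@dataclass
class AirwayCrossSection:
    """One branch's cross-section measurements (all lengths in mm)."""

    branch_label: str
    LA: float
    Pe: float
    Douter: float
    Dave: float

    def __post_init__(self) -> None:
        if self.LA <= 0 or self.Pe <= 0:
            raise ValueError(f"LA and Pe must be positive, got LA={self.LA}, Pe={self.Pe}")
        if not (self.Douter >= self.Dave > 0):
            raise ValueError(
                f"need Douter >= Dave > 0, got Douter={self.Douter}, Dave={self.Dave}"
            )
        # isoperimetric inequality: 4*pi*LA <= Pe^2, hence Dh <= Pe/pi
        if 4.0 * math.pi * self.LA > self.Pe ** 2 * (1.0 + 1e-9):
            raise ValueError(
                f"LA={self.LA} and Pe={self.Pe} violate the isoperimetric bound"
            )


@dataclass
class SubjectCovariates:
    """Predictors of the healthy-reference equations.

    Sex coding: 1 = male, 0 = female.  Height in meters.
    """

    age: float
    height: float
    sex: int

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if not (1.2 <= self.height <= 2.2):
            raise ValueError(f"height {self.height} m outside the plausible 1.2-2.2 m range")
        if self.sex not in (0, 1):
            raise ValueError(f"sex must be 0 (female) or 1 (male), got {self.sex}")


@dataclass
class PredictionEquation:
    """Configurable linear-in-terms reference equation.

    ``value = intercept + sum(coef * prod(factors))`` where each factor is one
    of ``log_age`` (natural log of age in years), ``log_height`` (natural log
    of height in meters), ``height2`` (height squared, m^2) and ``sex``
    (0/1).  ``intercept_log=True`` makes the intercept contribute
    ``log(intercept)``, matching the printed wall-thickness equation.
    """

    intercept: float
    terms: List[Tuple[float, Tuple[str, ...]]]
    intercept_log: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        for coef, factors in self.terms:
            unknown = set(factors) - _VALID_FACTORS
            if unknown:
                raise ValueError(f"unknown factors {sorted(unknown)} in equation {self.name!r}")

    def evaluate(self, cov: SubjectCovariates) -> float:
        basis = {
            "log_age": math.log(cov.age),
            "log_height": math.log(cov.height),
            "height2": cov.height ** 2,
            "sex": float(cov.sex),
        }
        total = math.log(self.intercept) if self.intercept_log else self.intercept
        for coef, factors in self.terms:
            total += coef * math.prod(basis[f] for f in factors)
        return total

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "intercept": self.intercept,
            "intercept_log": self.intercept_log,
            "terms": [{"coef": c, "factors": list(f)} for c, f in self.terms],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PredictionEquation":
        return cls(
            intercept=float(d["intercept"]),
            intercept_log=bool(d.get("intercept_log", False)),
            terms=[(float(t["coef"]), tuple(t["factors"])) for t in d["terms"]],
            name=str(d.get("name", "")),
        )

    @classmethod
    def from_yaml(cls, path) -> "PredictionEquation":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_dh_equation() -> PredictionEquation:
    """Printed healthy-reference equation for tracheal hydraulic diameter."""
    return PredictionEquation(
        name="trachea_dh",
        intercept=12.79,
        terms=[
            (-0.13, ("log_age",)),
            (-5.82, ("log_height", "sex")),
            (3.01, ("log_age", "log_height")),
        ],
    )


def default_wt_equation() -> PredictionEquation:
    """Printed healthy-reference equation for tracheal wall thickness."""
    return PredictionEquation(
        name="trachea_wt",
        intercept=9.11,
        intercept_log=True,
        terms=[
            (-1.02, ("log_age",)),
            (-0.98, ("height2", "sex")),
            (1.01, ("height2", "log_age")),
        ],
    )


def hydraulic_diameter(LA, Pe):
    """Hydraulic luminal diameter Dh = 4 LA / Pe (mm).

    Equals the geometric diameter for a circle and the side length for a
    square; accepts scalars or arrays.
    """
    LA = np.asarray(LA, dtype=float)
    Pe = np.asarray(Pe, dtype=float)
    if np.any(LA <= 0) or np.any(Pe <= 0):
        raise ValueError("LA and Pe must be positive")
    out = 4.0 * LA / Pe
    return float(out) if out.ndim == 0 else out


def wall_thickness(Douter, Dave):
    """Airway wall thickness WT = (D_outer - D_ave) / 2 (mm)."""
    Douter = np.asarray(Douter, dtype=float)
    Dave = np.asarray(Dave, dtype=float)
    if np.any(Dave <= 0) or np.any(Douter < Dave):
        raise ValueError("need Douter >= Dave > 0")
    out = (Douter - Dave) / 2.0
    return float(out) if out.ndim == 0 else out


def predicted_trachea_dh(cov: SubjectCovariates,
                         equation: Optional[PredictionEquation] = None) -> float:
    """Predicted healthy tracheal Dh (mm) for the subject's covariates."""
    return (equation or default_dh_equation()).evaluate(cov)


def predicted_trachea_wt(cov: SubjectCovariates,
                         equation: Optional[PredictionEquation] = None) -> float:
    """Predicted healthy tracheal WT (mm) for the subject's covariates."""
    return (equation or default_wt_equation()).evaluate(cov)


def normalize_metric(measured: float, predicted: float) -> float:
    """Measured value divided by its healthy-reference prediction."""
    if predicted <= 0:
        raise ValueError(f"predicted value must be positive, got {predicted}")
    return measured / predicted


def compute_airway_metrics(table: pd.DataFrame,
                           covariates: Optional[SubjectCovariates] = None,
                           dh_equation: Optional[PredictionEquation] = None,
                           wt_equation: Optional[PredictionEquation] = None) -> pd.DataFrame:
    """Per-branch Dh and WT (and normalized values when covariates given).

    ``table`` needs columns branch_label, LA_mm2, Pe_mm, Douter_mm, Dave_mm.
    Branches are passed through as given; aggregation of segmental airways to
    the five sub-lobar groups, when requested upstream, is the unweighted
    mean across member segments.
    """
    required = {"branch_label", "LA_mm2", "Pe_mm", "Douter_mm", "Dave_mm"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"airway table is missing columns {sorted(missing)}")
    out = table.copy()
    out["Dh_mm"] = hydraulic_diameter(out["LA_mm2"].to_numpy(), out["Pe_mm"].to_numpy())
    out["WT_mm"] = wall_thickness(out["Douter_mm"].to_numpy(), out["Dave_mm"].to_numpy())
    if covariates is not None:
        pred_dh = predicted_trachea_dh(covariates, dh_equation)
        pred_wt = predicted_trachea_wt(covariates, wt_equation)
        out["Dh_norm"] = out["Dh_mm"] / pred_dh
        out["WT_norm"] = out["WT_mm"] / pred_wt
    return out
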