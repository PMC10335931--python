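"""Linear fat-mass prediction equations: the model container and scoring.

A fitted equation is a plain linear form

    FM (kg) = intercept + sum_j coefficient_j * variable_j

over named anthropometric variables. The same container holds per-fold
partial models, aggregated final models, and the published equations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Union

import numpy as np

from .cohort import CohortTable, InfantRecord, Visit

__all__ = ["LinearFMModel", "predict_fm", "VARIABLE_SYMBOLS", "VARIABLE_UNITS"]

#: Field-standard short symbols used when rendering equations.
VARIABLE_SYMBOLS: Mapping[str, str] = {
    "sex": "sex",
    "gestational_age_birth": "gestational age at birth",
    "weight": "weight",
    "length": "length",
    "bmi": "BMI",
    "head_circ": "HC",
    "muac": "MUAC",
    "waist_circ": "WC",
    "thigh_circ": "TC",
    "calf_circ": "CC",
    "biceps_sf": "BSF",
    "triceps_sf": "TSF",
    "subscapular_sf": "SSF",
    "waist_sf": "WSF",
    "thigh_sf": "ThSF",
    "calf_sf": "CSF",
}

VARIABLE_UNITS: Mapping[str, str] = {
    "sex": "0=female/1=male",
    "gestational_age_birth": "weeks",
    "weight": "kg",
    "length": "cm",
    "bmi": "kg/m^2",
    "head_circ": "cm",
    "muac": "cm",
    "waist_circ": "cm",
    "thigh_circ": "cm",
    "calf_circ": "cm",
    "biceps_sf": "mm",
    "triceps_sf": "mm",
    "subscapular_sf": "mm",
    "waist_sf": "mm",
    "thigh_sf": "mm",
    "calf_sf": "mm",
}


@dataclass(frozen=True)
class LinearFMModel:
    """Intercept plus named coefficients predicting fat mass in kg."""

    visit: Visit
    variables: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "visit", Visit.coerce(self.visit))
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(
            self, "coefficients", tuple(float(c) for c in self.coefficients)
        )
        if len(self.variables) != len(self.coefficients):
            raise ValueError(
                f"{len(self.variables)} variables but {len(self.coefficients)} coefficients"
            )

    @classmethod
    def from_mapping(
        cls,
        visit: Union[Visit, str],
        coefficients: Mapping[str, float],
        intercept: float,
        provenance: str = "",
    ) -> "LinearFMModel":
        return cls(
            Visit.coerce(visit),
            tuple(coefficients.keys()),
            tuple(coefficients.values()),
            float(intercept),
            provenance,
        )

    @property
    def coef_map(self) -> dict[str, float]:
        return dict(zip(self.variables, self.coefficients))

    def predict_record(self, record: InfantRecord) -> float:
        """Predicted FM (kg) for one record; negative values are not clipped."""
        total = self.intercept
        for name, coef in zip(self.variables, self.coefficients):
            try:
                total += coef * record.value_of(name)
            except KeyError as exc:
                raise KeyError(
                    f"record {record.infant_id} is missing model variable {name!r}"
                ) from exc
        return total

    def predict_values(self, values: Mapping[str, float]) -> float:
        """Evaluate the equation at explicit variable values (e.g. sample means).

        For a linear model the prediction at the mean covariates equals
        the mean of the per-record predictions, so this doubles as the
        cohort-mean prediction.
        """
        total = self.intercept
        for name, coef in zip(self.variables, self.coefficients):
            if name not in values:
                raise KeyError(f"missing model variable {name!r}")
            total += coef * float(values[name])
        return total

    def predict(self, cohort: CohortTable) -> np.ndarray:
        """Predicted FM (kg) for every record, in table order."""
        X = cohort.design_matrix(self.variables)
        return self.intercept + X @ np.asarray(self.coefficients)

    def equation_string(self, decimals: int = 3) -> str:
        """Render in the conventional style, e.g. ``FM (kg) = 0.006(WC) + ... - 1.045``."""
        parts: list[str] = []
        for name, coef in zip(self.variables, self.coefficients):
            symbol = VARIABLE_SYMBOLS.get(name, name)
            term = f"{abs(coef):.{decimals}f}({symbol})"
            if not parts:
                parts.append(term if coef >= 0 else f"-{term}")
            else:
                parts.append(f"{'+' if coef >= 0 else '-'} {term}")
        sign = "+" if self.intercept >= 0 else "-"
        parts.append(f"{sign} {abs(self.intercept):.{decimals}f}")
        return "FM (kg) = " + " ".join(parts)

    def to_dict(self) -> dict:
        return {
            "visit": self.visit.value,
            "variables": list(self.variables),
            "units": [VARIABLE_UNITS.get(v, "") for v in self.variables],
            "coefficients": list(self.coefficients),
            "intercept": self.intercept,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "LinearFMModel":
        return cls(
            Visit.coerce(data["visit"]),
            tuple(data["variables"]),
            tuple(data["coefficients"]),
            float(data["intercept"]),
            str(data.get("provenance", "")),
        )

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )

    @classmethod
    def load(cls, path: Union[str, Path]) -> "LinearFMModel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def predict_fm(model: LinearFMModel, record: InfantRecord) -> float:
    """Predicted fat mass (kg) of `record` under `model`.

    Linear form: intercept + sum of coefficient times variable value.
    Predictions below zero are returned as-is (clipping would silently
    bias downstream agreement statistics); callers may flag them.
    """
    return model.predict_record(record)
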