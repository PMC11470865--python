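"""Age x education (x sex) correction grids for adjusting raw scores of
newly tested individuals.

Each cell holds the additive correction — the exact regression correction
evaluated at the cell's representative demographics (band midpoints).  Cells
whose demographic combination is unoccupied in the normative sample are
flagged ``extrapolated``, mirroring the published grid's asterisks; the
"extrapolation formula" is simply the globally valid regression equation.

Grids are built for free recall, recognition, failed recognition (by sex,
no education dimension) and total false memory.  Semantic and non-semantic
false memory need no demographic correction, so no grid exists for them
(stratified cut-offs are used instead).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .cohort import AGE_BAND_LABELS, AGE_BANDS, EDU_BAND_LABELS, band_occupancy
from .errors import DomainError, FrtError
from .normative import NormativeModel, Subscale

__all__ = [
    "REPRESENTATIVE_AGES",
    "REPRESENTATIVE_EDUCATION",
    "GRID_SUBSCALES",
    "DemographicBand",
    "CorrectionGrid",
    "correction_at",
    "build_grid",
    "adjust_via_grid",
]

GRID_SCHEMA_VERSION = 1

#: Band midpoints used as representative demographics per cell.
REPRESENTATIVE_AGES: Mapping[str, float] = {
    "18-30": 24.0,
    "30-39": 34.5,
    "40-49": 44.5,
    "50-59": 54.5,
    "60-69": 64.5,
    "70-79": 74.5,
    "80+": 85.0,
}
REPRESENTATIVE_EDUCATION: Mapping[str, float] = {
    "1-5": 3.0,
    "6-8": 7.0,
    "9-13": 11.0,
    "13+": 16.5,
}

#: Subscales that get a grid; failed recognition is keyed by sex instead of
#: education.
GRID_SUBSCALES = (
    Subscale.FREE_RECALL,
    Subscale.RECOGNITION,
    Subscale.FAILED_RECOGNITION,
    Subscale.TOTAL_FM,
)

# Lookup intervals: the shared 18/30 etc. boundaries are assigned to the
# younger band, the open bands absorb the rest of the covariate domain.
_AGE_LOOKUP = list(zip(AGE_BAND_LABELS, AGE_BANDS))
_EDU_LOOKUP = [("1-5", (0, 5)), ("6-8", (6, 8)), ("9-13", (9, 13)), ("13+", (14, 99))]


@dataclass(frozen=True)
class DemographicBand:
    age_band: str
    column: str  # education band, or "F"/"M" for the sex-keyed grid
    representative_age: float
    representative_column: float | str


def _age_band_of(age: float) -> str | None:
    for label, (lo, hi) in _AGE_LOOKUP:
        if lo <= age <= hi:
            return label
    if 80 <= age < 100:
        return "80+"
    return None


def _edu_band_of(education: float) -> str | None:
    for label, (lo, hi) in _EDU_LOOKUP:
        if lo <= education <= hi:
            return label
    return None


def correction_at(
    age: float,
    education: float | None,
    sex: str | None,
    model: NormativeModel,
    subscale: Subscale,
) -> float:
    """Exact additive correction: ``adjusted = raw + correction_at(...)``.

    Evaluates the regression formula directly (no grid).  Demographics must
    lie in the normative domain (age 18-99).  Covariates passed as ``None``
    are held at their centering value, contributing zero — this is how a
    grid keyed by fewer dimensions than the model marginalizes the rest.
    """
    if not 18 <= age < 100:
        raise DomainError(f"age {age} outside the normative domain [18, 100)")
    sub_model = model[subscale]
    spec = sub_model.transform
    covariates: dict[str, float] = {"age": spec.age(age)}
    if education is not None:
        covariates["education"] = spec.education(education)
    if sex is not None:
        covariates["sex"] = spec.sex(sex)
    total = 0.0
    for term in sub_model.terms:
        x = covariates.get(term.covariate, term.center)
        total -= term.coefficient * (x - term.center)
    return total


@dataclass
class CorrectionGrid:
    subscale: Subscale
    columns: tuple[str, ...]  # education bands or ("F", "M")
    cells: dict[tuple[str, str], float]  # (age band, column) -> correction
    extrapolated: dict[tuple[str, str], bool]
    by_sex: bool = False

    def correction(self, age_band: str, column: str) -> float:
        return self.cells[(age_band, column)]

    def to_frame(self, decimals: int = 2) -> pd.DataFrame:
        """Rendered grid (age-band rows x columns), values rounded for
        display; extrapolated cells carry a trailing ``*``."""
        data = {}
        for col in self.columns:
            data[col] = [
                f"{self.cells[(ab, col)]:.{decimals}f}"
                + ("*" if self.extrapolated[(ab, col)] else "")
                for ab in AGE_BAND_LABELS
            ]
        return pd.DataFrame(data, index=list(AGE_BAND_LABELS))

    def to_dict(self) -> dict:
        return {
            "schema_version": GRID_SCHEMA_VERSION,
            "kind": "correction_grid",
            "subscale": self.subscale.value,
            "by_sex": self.by_sex,
            "columns": list(self.columns),
            "cells": [
                {
                    "age_band": ab,
                    "column": col,
                    "correction": self.cells[(ab, col)],
                    "extrapolated": self.extrapolated[(ab, col)],
                }
                for (ab, col) in sorted(self.cells)
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "CorrectionGrid":
        if payload.get("kind") != "correction_grid":
            raise FrtError("artifact is not a correction_grid document")
        if payload.get("schema_version") != GRID_SCHEMA_VERSION:
            raise FrtError(
                f"unsupported correction_grid schema_version "
                f"{payload.get('schema_version')!r}"
            )
        cells = {}
        extrapolated = {}
        for cell in payload["cells"]:
            key = (cell["age_band"], cell["column"])
            cells[key] = float(cell["correction"])
            extrapolated[key] = bool(cell["extrapolated"])
        return cls(
            subscale=Subscale(payload["subscale"]),
            columns=tuple(payload["columns"]),
            cells=cells,
            extrapolated=extrapolated,
            by_sex=bool(payload["by_sex"]),
        )


def build_grid(model: NormativeModel, subscale: Subscale) -> CorrectionGrid:
    """Correction grid for one subscale at band-midpoint demographics."""
    if subscale not in GRID_SUBSCALES:
        raise FrtError(
            f"no correction grid is defined for {subscale.value} "
            "(cut-offs only)"
        )
    occupancy = band_occupancy()
    cells: dict[tuple[str, str], float] = {}
    extrapolated: dict[tuple[str, str], bool] = {}
    if subscale is Subscale.FAILED_RECOGNITION:
        columns: tuple[str, ...] = ("F", "M")
        for age_band in AGE_BAND_LABELS:
            for sex in columns:
                cells[(age_band, sex)] = correction_at(
                    REPRESENTATIVE_AGES[age_band], None, sex, model, subscale
                )
                extrapolated[(age_band, sex)] = False
        return CorrectionGrid(subscale, columns, cells, extrapolated, by_sex=True)

    columns = EDU_BAND_LABELS
    for age_band in AGE_BAND_LABELS:
        for edu_band in columns:
            cells[(age_band, edu_band)] = correction_at(
                REPRESENTATIVE_AGES[age_band],
                REPRESENTATIVE_EDUCATION[edu_band],
                None,
                model,
                subscale,
            )
            extrapolated[(age_band, edu_band)] = occupancy[(edu_band, age_band)] == 0
    return CorrectionGrid(subscale, columns, cells, extrapolated)


def adjust_via_grid(
    raw: float,
    age: float,
    education: float | None,
    sex: str | None,
    grid: CorrectionGrid,
    model: NormativeModel | None = None,
) -> tuple[float, str]:
    """Raw + cell correction; falls back to the exact formula off-grid.

    Returns ``(adjusted, method)`` with method ``"grid"`` or ``"formula"``.
    The fallback needs ``model``; without one, off-grid demographics raise.
    """
    age_band = _age_band_of(age)
    column: str | None
    if grid.by_sex:
        column = sex if sex in grid.columns else None
    else:
        column = _edu_band_of(education) if education is not None else None
    if age_band is not None and column is not None and (age_band, column) in grid.cells:
        return raw + grid.cells[(age_band, column)], "grid"
    if model is None:
        raise DomainError(
            f"demographics (age={age}, education={education}, sex={sex}) fall "
            "outside the grid and no model was supplied for formula fallback"
        )
    return raw + correction_at(age, education, sex, model, grid.subscale), "formula"
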