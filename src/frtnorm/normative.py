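"""Demographic covariate transforms, normative regression models and
raw -> adjusted score conversion.

Adjustment follows the regression-based norming tradition: each raw
subscore is regressed on transformed demographics (age as log10(100 - age),
education as sqrt of schooling years, sex as a centered male indicator) and
the fitted demographic contribution is removed around the normative-sample
centering constants,

    adjusted = raw - sum_j  B_j * (x_j - c_j)

with ``B_j`` the *signed* unstandardized coefficient from the regression of
the raw score.  For scales where high scores are good, coefficients are
positive and older / less educated subjects receive a positive correction;
for error scales the signs flip automatically.

:data:`PUBLISHED_MODEL` stores the published coefficient set verbatim
(centering constants 1.69 for transformed age, 3.54 for transformed
education, sex coded female = -0.42 / male = 0.58).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, FrtError, SchemaError

__all__ = [
    "Subscale",
    "Orientation",
    "TransformSpec",
    "SubjectRecord",
    "ModelTerm",
    "SubscaleModel",
    "NormativeModel",
    "PUBLISHED_MODEL",
    "SUBSCALE_COLUMNS",
    "transform_covariates",
    "adjust_score",
    "fit_normative_model",
    "fit_all_subscales",
    "internal_correlations",
    "read_cohort_csv",
    "cohort_to_frame",
]

MODEL_SCHEMA_VERSION = 1


class Subscale(str, enum.Enum):
    FREE_RECALL = "free_recall"
    RECOGNITION = "recognition"
    FAILED_RECOGNITION = "failed_recognition"
    SEMANTIC_FM = "semantic_fm"
    NON_SEMANTIC_FM = "non_semantic_fm"
    TOTAL_FM = "total_fm"


#: Cohort-CSV column name per subscale (identical to the enum values).
SUBSCALE_COLUMNS = [s.value for s in Subscale]


class Orientation(str, enum.Enum):
    HIGHER_BETTER = "higher_better"
    HIGHER_WORSE = "higher_worse"


ORIENTATIONS: Mapping[Subscale, Orientation] = {
    Subscale.FREE_RECALL: Orientation.HIGHER_BETTER,
    Subscale.RECOGNITION: Orientation.HIGHER_BETTER,
    Subscale.FAILED_RECOGNITION: Orientation.HIGHER_WORSE,
    Subscale.SEMANTIC_FM: Orientation.HIGHER_WORSE,
    Subscale.NON_SEMANTIC_FM: Orientation.HIGHER_WORSE,
    Subscale.TOTAL_FM: Orientation.HIGHER_WORSE,
}


@dataclass(frozen=True)
class TransformSpec:
    """Covariate transforms used by fitting and adjustment.

    ``education_transform`` is ``"sqrt"`` for every scale except the
    failed-recognition screening path, which used raw schooling years.
    """

    education_transform: str = "sqrt"  # "sqrt" | "identity"
    sex_code_female: float = -0.42
    sex_code_male: float = 0.58

    def age(self, age_years: float) -> float:
        if age_years >= 100:
            raise DomainError(f"age {age_years} >= 100: log10(100 - age) undefined")
        if age_years < 0:
            raise DomainError(f"age {age_years} is negative")
        return math.log10(100.0 - age_years)

    def education(self, years: float) -> float:
        if years < 0:
            raise DomainError(f"education {years} is negative")
        if self.education_transform == "sqrt":
            return math.sqrt(years)
        if self.education_transform == "identity":
            return float(years)
        raise FrtError(f"unknown education_transform {self.education_transform!r}")

    def sex(self, sex: str) -> float:
        s = sex.strip().upper()
        if s in ("M", "MALE"):
            return self.sex_code_male
        if s in ("F", "FEMALE"):
            return self.sex_code_female
        raise DomainError(f"unknown sex code {sex!r} (expected M/F)")


DEFAULT_TRANSFORMS: Mapping[Subscale, TransformSpec] = {
    sub: (
        TransformSpec(education_transform="identity")
        if sub is Subscale.FAILED_RECOGNITION
        else TransformSpec()
    )
    for sub in Subscale
}


@dataclass
class SubjectRecord:
    subject_id: str
    age: float
    sex: str | None  # "M" / "F"
    education: float
    scores: Mapping[str, float] = field(default_factory=dict)


def transform_covariates(
    record: SubjectRecord, spec: TransformSpec | None = None
) -> dict[str, float]:
    """Return the transformed covariate vector ``{age, education, sex}``.

    Sex is omitted from the result when the record carries none.
    """
    spec = spec or TransformSpec()
    out = {
        "age": spec.age(record.age),
        "education": spec.education(record.education),
    }
    if record.sex is not None:
        out["sex"] = spec.sex(record.sex)
    return out


@dataclass(frozen=True)
class ModelTerm:
    """One retained predictor: signed coefficient and centering constant."""

    covariate: str  # "age" | "education" | "sex"
    coefficient: float
    center: float


@dataclass
class SubscaleModel:
    subscale: Subscale
    terms: tuple[ModelTerm, ...]
    orientation: Orientation
    transform: TransformSpec = field(default_factory=TransformSpec)
    fit_stats: dict[str, float] = field(default_factory=dict)

    def correction(self, covariates: Mapping[str, float]) -> float:
        """Additive correction such that adjusted = raw + correction."""
        total = 0.0
        for term in self.terms:
            if term.covariate not in covariates:
                raise DomainError(
                    f"{self.subscale.value}: model requires covariate "
                    f"{term.covariate!r} which is missing from the record"
                )
            total -= term.coefficient * (covariates[term.covariate] - term.center)
        return total


@dataclass
class NormativeModel:
    models: dict[Subscale, SubscaleModel]
    source: str = "published"

    def __getitem__(self, subscale: Subscale) -> SubscaleModel:
        try:
            return self.models[subscale]
        except KeyError:
            raise FrtError(f"no model stored for subscale {subscale!r}") from None

    def to_dict(self) -> dict:
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "kind": "normative_model",
            "source": self.source,
            "subscales": {
                sub.value: {
                    "orientation": m.orientation.value,
                    "education_transform": m.transform.education_transform,
                    "sex_codes": {
                        "F": m.transform.sex_code_female,
                        "M": m.transform.sex_code_male,
                    },
                    "terms": [
                        {
                            "covariate": t.covariate,
                            "coefficient": t.coefficient,
                            "center": t.center,
                        }
                        for t in m.terms
                    ],
                    "fit_stats": dict(m.fit_stats),
                }
                for sub, m in self.models.items()
            },
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "NormativeModel":
        if payload.get("kind") != "normative_model":
            raise SchemaError("artifact is not a normative_model document")
        if payload.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise SchemaError(
                f"unsupported normative_model schema_version "
                f"{payload.get('schema_version')!r}"
            )
        models: dict[Subscale, SubscaleModel] = {}
        for name, doc in payload["subscales"].items():
            sub = Subscale(name)
            spec = TransformSpec(
                education_transform=doc.get("education_transform", "sqrt"),
                sex_code_female=doc["sex_codes"]["F"],
                sex_code_male=doc["sex_codes"]["M"],
            )
            models[sub] = SubscaleModel(
                subscale=sub,
                terms=tuple(
                    ModelTerm(t["covariate"], float(t["coefficient"]), float(t["center"]))
                    for t in doc["terms"]
                ),
                orientation=Orientation(doc["orientation"]),
                transform=spec,
                fit_stats={k: float(v) for k, v in doc.get("fit_stats", {}).items()},
            )
        return cls(models=models, source=payload.get("source", "unknown"))


# Published coefficient set.  Signs are the regression coefficients of the
# raw score on the transformed covariates, so the subtraction in
# SubscaleModel.correction reproduces the printed adjustment formulas
# exactly (error scales get "+" corrections through their negative B).
_C_AGE = 1.69
_C_EDU = 3.54

PUBLISHED_MODEL = NormativeModel(
    source="published",
    models={
        Subscale.FREE_RECALL: SubscaleModel(
            Subscale.FREE_RECALL,
            (
                ModelTerm("age", 10.23, _C_AGE),
                ModelTerm("education", 2.317, _C_EDU),
            ),
            Orientation.HIGHER_BETTER,
            fit_stats={"R": 0.705, "R2": 0.497, "F": 113.113},
        ),
        Subscale.RECOGNITION: SubscaleModel(
            Subscale.RECOGNITION,
            (
                ModelTerm("age", 6.771, _C_AGE),
                ModelTerm("education", 0.693, _C_EDU),
            ),
            Orientation.HIGHER_BETTER,
            fit_stats={"R": 0.609, "R2": 0.376, "F": 7.385},
        ),
        Subscale.FAILED_RECOGNITION: SubscaleModel(
            Subscale.FAILED_RECOGNITION,
            (
                ModelTerm("age", -3.099, _C_AGE),
                ModelTerm("sex", 0.601, 0.0),
            ),
            Orientation.HIGHER_WORSE,
            fit_stats={"R": 0.368, "R2": 0.135, "F": 17.897},
        ),
        Subscale.SEMANTIC_FM: SubscaleModel(
            Subscale.SEMANTIC_FM,
            (ModelTerm("age", -3.553, _C_AGE),),
            Orientation.HIGHER_WORSE,
            fit_stats={"R": 0.381, "R2": 0.145, "F": 39.125},
        ),
        Subscale.NON_SEMANTIC_FM: SubscaleModel(
            Subscale.NON_SEMANTIC_FM,
            (
                ModelTerm("age", -1.19, _C_AGE),
                ModelTerm("education", -0.261, _C_EDU),
            ),
            Orientation.HIGHER_WORSE,
            fit_stats={"R": 0.583, "R2": 0.339, "F": 58.805},
        ),
        Subscale.TOTAL_FM: SubscaleModel(
            Subscale.TOTAL_FM,
            (
                ModelTerm("age", -3.837, _C_AGE),
                ModelTerm("education", -0.698, _C_EDU),
            ),
            Orientation.HIGHER_WORSE,
            fit_stats={"R": 0.507, "R2": 0.257, "F": 39.553},
        ),
    },
)


def adjust_score(
    raw: float,
    record: SubjectRecord,
    model: NormativeModel,
    subscale: Subscale,
) -> float:
    """Demographically adjusted score (real-valued; round only for display)."""
    sub_model = model[subscale]
    covariates = transform_covariates(record, sub_model.transform)
    return raw + sub_model.correction(covariates)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

_CANDIDATES = ("age", "sex", "education")


def _design_frame(
    cohort: Sequence[SubjectRecord], subscale: Subscale, spec: TransformSpec
) -> pd.DataFrame:
    rows = []
    for rec in cohort:
        if rec.sex is None:
            raise DomainError(f"subject {rec.subject_id!r}: sex required for fitting")
        male = 1.0 if spec.sex(rec.sex) == spec.sex_code_male else 0.0
        rows.append(
            {
                "age": spec.age(rec.age),
                "education": spec.education(rec.education),
                "male": male,
                "y": float(rec.scores[subscale.value]),
            }
        )
    return pd.DataFrame(rows)


def fit_normative_model(
    cohort: Sequence[SubjectRecord],
    subscale: Subscale,
    spec: TransformSpec | None = None,
    alpha: float = 0.05,
) -> SubscaleModel:
    """OLS of the raw subscore on transformed demographics.

    All three candidate covariates enter a multiple regression; predictors
    with p < ``alpha`` are retained and the model refitted on them alone.
    Centering constants are the cohort means of the transformed covariates
    (the sex code is the male indicator centered on the cohort male share,
    so its centering constant is 0 by construction).
    """
    import statsmodels.api as sm

    if len(cohort) < 30:
        raise FrtError(f"cohort too small to fit a normative model (n={len(cohort)})")
    spec = spec or DEFAULT_TRANSFORMS[subscale]
    frame = _design_frame(cohort, subscale, spec)

    male_share = frame["male"].mean()
    frame["sex"] = frame["male"] - male_share
    centers = {
        "age": frame["age"].mean(),
        "education": frame["education"].mean(),
        "sex": 0.0,
    }
    for cov in _CANDIDATES:
        if frame[cov].std(ddof=0) == 0.0:
            raise FrtError(
                f"{subscale.value}: covariate {cov!r} is constant in the cohort; "
                "design is rank-deficient"
            )

    def _ols(covs: Sequence[str]):
        X = sm.add_constant(frame[list(covs)])
        return sm.OLS(frame["y"], X).fit()

    full = _ols(_CANDIDATES)
    retained = tuple(c for c in _CANDIDATES if full.pvalues[c] < alpha)
    final = _ols(retained) if retained else None

    terms = tuple(
        ModelTerm(c, float(final.params[c]), centers[c]) for c in retained
    )
    if final is not None:
        fit_stats = {
            "R": float(np.sqrt(max(final.rsquared, 0.0))),
            "R2": float(final.rsquared),
            "F": float(final.fvalue),
            "p": float(final.f_pvalue),
            "n": float(len(cohort)),
        }
    else:
        fit_stats = {"R": 0.0, "R2": 0.0, "n": float(len(cohort))}
    return SubscaleModel(
        subscale=subscale,
        terms=terms,
        orientation=ORIENTATIONS[subscale],
        transform=spec,
        fit_stats=fit_stats,
    )


def fit_all_subscales(
    cohort: Sequence[SubjectRecord], alpha: float = 0.05
) -> NormativeModel:
    return NormativeModel(
        models={sub: fit_normative_model(cohort, sub, alpha=alpha) for sub in Subscale},
        source="fitted",
    )


def internal_correlations(
    cohort: Sequence[SubjectRecord] | pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided p over the six subscores.

    Zero-variance columns yield NaN entries (r undefined) rather than an
    error.  Used to validate synthetic cohorts against the published
    within-test correlation block.
    """
    if isinstance(cohort, pd.DataFrame):
        frame = cohort[SUBSCALE_COLUMNS]
    else:
        frame = pd.DataFrame([{c: rec.scores[c] for c in SUBSCALE_COLUMNS} for rec in cohort])
    if len(frame) < 3:
        raise FrtError("need at least 3 subjects for correlations")
    cols = SUBSCALE_COLUMNS
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            x, y = frame[a].to_numpy(float), frame[b].to_numpy(float)
            if x.std() == 0.0 or y.std() == 0.0:
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            res = stats.pearsonr(x, y)
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
    return r, p


# ---------------------------------------------------------------------------
# Cohort CSV dialect: subject_id, age, sex {M,F}, education + six subscores
# ---------------------------------------------------------------------------

COHORT_COLUMNS = ["subject_id", "age", "sex", "education", *SUBSCALE_COLUMNS]


def read_cohort_csv(path) -> list[SubjectRecord]:
    frame = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"cohort CSV missing columns: {missing}")
    records = []
    for _, row in frame.iterrows():
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                education=float(row["education"]),
                scores={c: float(row[c]) for c in SUBSCALE_COLUMNS},
            )
        )
    return records


def cohort_to_frame(cohort: Iterable[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for rec in cohort:
        rows.append(
            {
                "subject_id": rec.subject_id,
                "age": rec.age,
                "sex": rec.sex,
                "education": rec.education,
                **{c: rec.scores.get(c) for c in SUBSCALE_COLUMNS},
            }
        )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
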