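"""Synthetic normative-cohort generator.

Re-creates the structure of the normative sample so the whole pipeline can
be exercised without the study's (unreleased) raw data:

* demographics drawn from the published age-decade x education-band x sex
  frequency table (n = 232, 98 male);
* four subscores (free recall, failed recognition, semantic and
  non-semantic false memory) drawn from the published linear demographic
  models plus Gaussian noise and two latent person factors — a general
  memory-ability factor (good recall, few misses) and a response-bias
  factor (liberal responders endorse everything: fewer misses, more false
  memories) — which induce the observed off-diagonal correlations;
* the two structural scores derived exactly:
  ``total_fm = semantic_fm + non_semantic_fm`` and
  ``recognition = 36 - failed_recognition - total_fm``.

Noise scales, latent loadings and intercept offsets are frozen from a
one-off moment-matching calibration (see :mod:`frtnorm.calibration`) so the
*discretized* marginals reproduce the published means/SDs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .normative import Subscale, SubjectRecord, TransformSpec

__all__ = [
    "AGE_BANDS",
    "EDU_BANDS",
    "TABLE1_COUNTS",
    "TABLE1_MALE_SHARE",
    "CohortConfig",
    "sample_demographics",
    "generate_score_arrays",
    "generate_scores",
    "generate_cohort",
    "band_occupancy",
]

# ---------------------------------------------------------------------------
# Published demographic frequency table
# ---------------------------------------------------------------------------

#: Age decades (inclusive year ranges) in table order.
AGE_BANDS: tuple[tuple[int, int], ...] = (
    (18, 29),
    (30, 39),
    (40, 49),
    (50, 59),
    (60, 69),
    (70, 79),
    (80, 91),
)
AGE_BAND_LABELS = ("18-30", "30-39", "40-49", "50-59", "60-69", "70-79", "80+")

#: Education bands (schooling years) in table order.
EDU_BAND_LABELS = ("1-5", "6-8", "9-13", "13+")
EDU_BANDS: Mapping[str, tuple[int, int]] = {
    "1-5": (2, 5),  # sample minimum is 2 years
    "6-8": (6, 8),
    "9-13": (9, 13),
    "13+": (14, 20),
}

#: (female, male) counts per education band x age decade; row sums
#: 23 / 26 / 92 / 91, grand total 232 with 98 males.
TABLE1_COUNTS: Mapping[str, tuple[tuple[int, int], ...]] = {
    "1-5": ((0, 0), (0, 0), (1, 0), (0, 0), (2, 0), (8, 1), (8, 3)),
    "6-8": ((1, 3), (0, 0), (1, 1), (4, 2), (4, 2), (3, 2), (0, 3)),
    "9-13": ((17, 22), (1, 5), (8, 1), (12, 4), (3, 8), (6, 3), (2, 0)),
    "13+": ((31, 23), (7, 3), (1, 4), (10, 6), (3, 2), (1, 0), (0, 0)),
}

TABLE1_TOTAL = sum(f + m for row in TABLE1_COUNTS.values() for f, m in row)
TABLE1_MALE_SHARE = (
    sum(m for row in TABLE1_COUNTS.values() for _, m in row) / TABLE1_TOTAL
)

# Within-band schooling-year distributions.  Mass sits on the Italian
# qualification milestones (5 elementary, 8 middle school, 13 diploma,
# 18 degree) and is tuned so mean(sqrt(education)) over the cohort matches
# the published centering constant 3.54.
_EDU_YEAR_WEIGHTS: Mapping[str, tuple[tuple[int, float], ...]] = {
    "1-5": ((2, 0.1), (3, 0.2), (4, 0.1), (5, 0.6)),
    "6-8": ((6, 0.15), (7, 0.1), (8, 0.75)),
    "9-13": ((9, 0.05), (10, 0.05), (11, 0.1), (12, 0.1), (13, 0.7)),
    "13+": ((14, 0.03), (15, 0.05), (16, 0.22), (17, 0.1), (18, 0.5), (19, 0.03), (20, 0.07)),
}


def band_occupancy() -> dict[tuple[str, str], int]:
    """Total subject count per (education band, age band) cell."""
    return {
        (edu, AGE_BAND_LABELS[j]): f + m
        for edu, row in TABLE1_COUNTS.items()
        for j, (f, m) in enumerate(row)
    }


# ---------------------------------------------------------------------------
# Generating model defaults
# ---------------------------------------------------------------------------

#: Subscales drawn directly from a linear model (the other two are derived).
GENERATED_SUBSCALES = (
    Subscale.FREE_RECALL,
    Subscale.FAILED_RECOGNITION,
    Subscale.SEMANTIC_FM,
    Subscale.NON_SEMANTIC_FM,
)

#: Published signed coefficients on (log10(100-age), sqrt(education), sex).
DEFAULT_COEFFICIENTS: Mapping[str, Mapping[str, float]] = {
    Subscale.FREE_RECALL.value: {"age": 10.23, "education": 2.317},
    Subscale.FAILED_RECOGNITION.value: {"age": -3.099, "sex": 0.601},
    Subscale.SEMANTIC_FM.value: {"age": -3.553},
    Subscale.NON_SEMANTIC_FM.value: {"age": -1.19, "education": -0.261},
}

#: Published sample means (the linear predictor at the centering point).
DEFAULT_INTERCEPTS: Mapping[str, float] = {
    Subscale.FREE_RECALL.value: 17.49,
    Subscale.FAILED_RECOGNITION.value: 2.15,
    Subscale.SEMANTIC_FM.value: 4.24,
    Subscale.NON_SEMANTIC_FM.value: 0.26,
}

#: Score ranges for clamping when discretizing.
SCORE_RANGES: Mapping[str, tuple[int, int]] = {
    Subscale.FREE_RECALL.value: (0, 36),
    Subscale.FAILED_RECOGNITION.value: (0, 18),
    Subscale.SEMANTIC_FM.value: (0, 9),
    Subscale.NON_SEMANTIC_FM.value: (0, 9),
}

# Frozen calibration output (see frtnorm.calibration; regenerate with
# `python -m frtnorm.calibration`).  intercept_offset is added to the
# published mean before discretization so the rounded/clamped marginal
# lands back on it.
CALIBRATED_NOISE_SD: dict[str, float] = {
    Subscale.FREE_RECALL.value: 3.0406,
    Subscale.FAILED_RECOGNITION.value: 1.3019,
    Subscale.SEMANTIC_FM.value: 1.2856,
    Subscale.NON_SEMANTIC_FM.value: 1.4342,
}
CALIBRATED_INTERCEPT_OFFSET: dict[str, float] = {
    Subscale.FREE_RECALL.value: -0.0645,
    Subscale.FAILED_RECOGNITION.value: -0.2067,
    Subscale.SEMANTIC_FM.value: 0.0279,
    # strongly negative: the zero-inflated non-semantic marginal is
    # emulated by censoring a wide Gaussian at the score floor.
    Subscale.NON_SEMANTIC_FM.value: -1.7006,
}
#: Loadings on the (ability, bias) latent factors.
CALIBRATED_LOADINGS: dict[str, tuple[float, float]] = {
    Subscale.FREE_RECALL.value: (1.5, 0.0),
    Subscale.FAILED_RECOGNITION.value: (-1.49, -0.674),
    Subscale.SEMANTIC_FM.value: (0.0, 1.39),
    Subscale.NON_SEMANTIC_FM.value: (0.0, 1.3102),
}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator."""

    n: int = TABLE1_TOTAL
    seed: int = 0
    demographic_source: str = "table1_frequencies"  # or "uniform"
    coefficients: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COEFFICIENTS.items()}
    )
    intercepts: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTERCEPTS)
    )
    intercept_offsets: Mapping[str, float] = field(
        default_factory=lambda: dict(CALIBRATED_INTERCEPT_OFFSET)
    )
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(CALIBRATED_NOISE_SD)
    )
    latent_loadings: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(CALIBRATED_LOADINGS)
    )
    discretize: bool = True
    male_share: float = TABLE1_MALE_SHARE
    center_age: float = 1.69
    center_education: float = 3.54

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        for scale, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise_sd[{scale!r}] must be >= 0, got {sd}")
        for scale, (lo, hi) in SCORE_RANGES.items():
            mu = self.intercepts[scale]
            if not lo <= mu <= hi:
                raise ValueError(
                    f"intercept {mu} for {scale!r} outside score range [{lo}, {hi}]"
                )

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def _sample_education_years(band: str, size: int, rng: np.random.Generator) -> np.ndarray:
    years, weights = zip(*_EDU_YEAR_WEIGHTS[band])
    p = np.asarray(weights, dtype=float)
    return rng.choice(np.asarray(years), size=size, p=p / p.sum())


def sample_demographics(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw ``(age, sex, education)`` rows; deterministic under a fixed seed."""
    rng = rng or np.random.default_rng(config.seed)
    n = config.n
    if config.demographic_source == "uniform":
        age = rng.integers(18, 92, size=n)
        education = rng.integers(2, 21, size=n)
        male = rng.random(n) < config.male_share
    elif config.demographic_source == "table1_frequencies":
        cells = []
        weights = []
        for edu_label, row in TABLE1_COUNTS.items():
            for j, (f, m) in enumerate(row):
                if f:
                    cells.append((edu_label, j, False))
                    weights.append(f)
                if m:
                    cells.append((edu_label, j, True))
                    weights.append(m)
        p = np.asarray(weights, dtype=float)
        idx = rng.choice(len(cells), size=n, p=p / p.sum())
        age = np.empty(n, dtype=int)
        education = np.empty(n, dtype=int)
        male = np.empty(n, dtype=bool)
        for i, cell_index in enumerate(idx):
            edu_label, band_j, is_male = cells[cell_index]
            lo, hi = AGE_BANDS[band_j]
            age[i] = rng.integers(lo, hi + 1)
            education[i] = _sample_education_years(edu_label, 1, rng)[0]
            male[i] = is_male
    else:
        raise ValueError(
            f"unknown demographic_source {config.demographic_source!r} "
            "(expected 'table1_frequencies' or 'uniform')"
        )
    return pd.DataFrame(
        {
            "age": age.astype(int),
            "sex": np.where(male, "M", "F"),
            "education": education.astype(int),
        }
    )


def _linear_predictors(
    demographics: pd.DataFrame, config: CohortConfig
) -> dict[str, np.ndarray]:
    spec = TransformSpec()
    z = np.log10(100.0 - demographics["age"].to_numpy(float)) - config.center_age
    w = np.sqrt(demographics["education"].to_numpy(float)) - config.center_education
    s = np.where(
        demographics["sex"].to_numpy() == "M", spec.sex_code_male, spec.sex_code_female
    )
    covs = {"age": z, "education": w, "sex": s}
    out = {}
    for sub in GENERATED_SUBSCALES:
        scale = sub.value
        slope = np.zeros(len(demographics))
        for cov, beta in config.coefficients[scale].items():
            slope = slope + beta * covs[cov]
        # nominal predictor (published intercept) drives the range warning;
        # the calibration offset is an internal censoring device and is
        # added afterwards.
        nominal = config.intercepts[scale] + slope
        out[scale] = (nominal + config.intercept_offsets.get(scale, 0.0), nominal)
    return out


def generate_score_arrays(
    demographics: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Vectorized scoring: one array per subscale, aligned to the rows.

    Warns when a configured linear predictor puts more than half the cohort
    outside the printed score range before clamping.
    """
    rng = rng or np.random.default_rng(config.seed)
    n = len(demographics)
    eta = _linear_predictors(demographics, config)
    ability = rng.standard_normal(n)
    bias = rng.standard_normal(n)

    raw: dict[str, np.ndarray] = {}
    for sub in GENERATED_SUBSCALES:
        scale = sub.value
        lam_a, lam_b = config.latent_loadings.get(scale, (0.0, 0.0))
        noise = config.noise_sd[scale] * rng.standard_normal(n)
        predictor, nominal = eta[scale]
        values = predictor + lam_a * ability + lam_b * bias + noise
        lo, hi = SCORE_RANGES[scale]
        out_of_range = np.mean((nominal < lo) | (nominal > hi))
        if out_of_range > 0.5:
            warnings.warn(
                f"{scale}: configured mean outside [{lo}, {hi}] for "
                f"{out_of_range:.0%} of subjects",
                stacklevel=2,
            )
        if config.discretize:
            values = np.clip(np.rint(values), lo, hi)
        raw[scale] = values

    raw[Subscale.TOTAL_FM.value] = (
        raw[Subscale.SEMANTIC_FM.value] + raw[Subscale.NON_SEMANTIC_FM.value]
    )
    raw[Subscale.RECOGNITION.value] = (
        36.0 - raw[Subscale.FAILED_RECOGNITION.value] - raw[Subscale.TOTAL_FM.value]
    )
    return raw


def generate_scores(
    demographics: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> list[SubjectRecord]:
    """Attach the six subscores to sampled demographics as subject records."""
    raw = generate_score_arrays(demographics, config, rng)
    ages = demographics["age"].to_numpy(float)
    sexes = demographics["sex"].to_numpy(str)
    edus = demographics["education"].to_numpy(float)
    scales = list(raw)
    records = []
    for i in range(len(demographics)):
        records.append(
            SubjectRecord(
                subject_id=f"sim{i:05d}",
                age=ages[i],
                sex=sexes[i],
                education=edus[i],
                scores={scale: float(raw[scale][i]) for scale in scales},
            )
        )
    return records


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Sample demographics and scores with a single seeded generator."""
    rng = np.random.default_rng(config.seed)
    demographics = sample_demographics(config, rng)
    return generate_scores(demographics, config, rng)
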