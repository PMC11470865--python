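import math

import numpy as np
import pandas as pd
import pytest

from frtnorm.cohort import CohortConfig, generate_cohort
from frtnorm.errors import DomainError, FrtError
from frtnorm.normative import (
    PUBLISHED_MODEL,
    NormativeModel,
    Orientation,
    SubjectRecord,
    Subscale,
    TransformSpec,
    adjust_score,
    fit_normative_model,
    internal_correlations,
    transform_covariates,
)

#: Demographics at which every transformed covariate equals its centering
#: constant, so adjustment must be the identity.
CENTER_AGE = 100.0 - 10.0**1.69  # log10(100 - age) == 1.69
CENTER_EDU = 3.54**2  # sqrt(education) == 3.54


def record(age=50, sex="F", education=12, **scores) -> SubjectRecord:
    return SubjectRecord("t", age, sex, education, scores)


class TestTransforms:
    def test_age_90_is_power_of_ten(self):
        assert TransformSpec().age(90) == 1.0

    def test_education_16_is_perfect_square(self):
        assert TransformSpec().education(16) == 4.0

    def test_hand_arithmetic(self):
        spec = TransformSpec()
        assert spec.age(51) == pytest.approx(math.log10(49), abs=1e-15)
        assert spec.education(12) == pytest.approx(math.sqrt(12), abs=1e-15)

    def test_identity_education_transform(self):
        spec = TransformSpec(education_transform="identity")
        assert spec.education(12) == 12.0

    def test_age_domain(self):
        with pytest.raises(DomainError):
            TransformSpec().age(100)
        with pytest.raises(DomainError):
            TransformSpec().age(120)

    def test_education_domain(self):
        with pytest.raises(DomainError):
            TransformSpec().education(-1)

    def test_sex_codes(self):
        spec = TransformSpec()
        assert spec.sex("M") == 0.58
        assert spec.sex("female") == -0.42
        with pytest.raises(DomainError):
            spec.sex("X")

    def test_transform_covariates_vector(self):
        out = transform_covariates(record(age=90, sex="M", education=16))
        assert out == {"age": 1.0, "education": 4.0, "sex": 0.58}

    def test_monotonicity(self):
        spec = TransformSpec()
        ages = np.arange(18, 100)
        t = [spec.age(a) for a in ages]
        assert all(x > y for x, y in zip(t, t[1:]))  # strictly decreasing
        edus = np.arange(0, 21)
        u = [spec.education(e) for e in edus]
        assert all(x < y for x, y in zip(u, u[1:]))


class TestAdjustScore:
    @pytest.mark.parametrize("subscale", list(Subscale))
    @pytest.mark.parametrize("raw", [0.0, 4.0, 17.49, 36.0])
    def test_centering_identity(self, subscale, raw):
        rec = record(age=CENTER_AGE, sex="F", education=CENTER_EDU)
        # sex code -0.42 is not the centered 0, so pick a subscale-appropriate
        # check: the failed-recognition model carries a sex term, all others
        # must be exactly the identity.
        adjusted = adjust_score(raw, rec, PUBLISHED_MODEL, subscale)
        if subscale is Subscale.FAILED_RECOGNITION:
            assert adjusted == pytest.approx(raw - 0.601 * (-0.42), abs=1e-12)
        else:
            assert adjusted == pytest.approx(raw, abs=1e-12)

    def test_semantic_fm_age_80(self):
        # oracle: direct evaluation of the printed formula
        expected = 4.0 + 3.553 * (math.log10(20) - 1.69)
        got = adjust_score(
            4.0, record(age=80), PUBLISHED_MODEL, Subscale.SEMANTIC_FM
        )
        assert got == pytest.approx(expected, abs=1e-12)
        assert got - 4.0 == pytest.approx(-1.382, abs=5e-4)

    def test_failed_recognition_age_90_female(self):
        expected = 2.0 + 3.099 * (1.0 - 1.69) - 0.601 * (-0.42)
        got = adjust_score(
            2.0, record(age=90, sex="F"), PUBLISHED_MODEL, Subscale.FAILED_RECOGNITION
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_free_recall_formula_verbatim(self):
        rec = record(age=70, sex="M", education=8)
        expected = 20.0 - 10.23 * (math.log10(30) - 1.69) - 2.317 * (
            math.sqrt(8) - 3.54
        )
        assert adjust_score(
            20.0, rec, PUBLISHED_MODEL, Subscale.FREE_RECALL
        ) == pytest.approx(expected, abs=1e-12)

    def test_missing_sex_errors_when_required(self):
        rec = SubjectRecord("t", 50, None, 12, {})
        with pytest.raises(DomainError, match="sex"):
            adjust_score(2.0, rec, PUBLISHED_MODEL, Subscale.FAILED_RECOGNITION)

    def test_unknown_subscale_errors(self):
        empty = NormativeModel(models={})
        with pytest.raises(FrtError, match="no model stored"):
            adjust_score(1.0, record(), empty, Subscale.FREE_RECALL)

    @pytest.mark.parametrize(
        "subscale",
        [Subscale.FREE_RECALL, Subscale.RECOGNITION],
    )
    def test_sign_higher_better(self, subscale):
        """Older subjects gain, better-educated subjects lose correction."""
        young = adjust_score(10, record(age=25), PUBLISHED_MODEL, subscale)
        old = adjust_score(10, record(age=85), PUBLISHED_MODEL, subscale)
        assert old > young
        low = adjust_score(10, record(education=5), PUBLISHED_MODEL, subscale)
        high = adjust_score(10, record(education=18), PUBLISHED_MODEL, subscale)
        assert low > high

    @pytest.mark.parametrize(
        "subscale",
        [Subscale.SEMANTIC_FM, Subscale.NON_SEMANTIC_FM, Subscale.TOTAL_FM],
    )
    def test_sign_higher_worse(self, subscale):
        young = adjust_score(4, record(age=25), PUBLISHED_MODEL, subscale)
        old = adjust_score(4, record(age=85), PUBLISHED_MODEL, subscale)
        assert old < young

    def test_sign_finite_differences_grid(self):
        """Corrections move monotonically with age/education everywhere."""
        for subscale in Subscale:
            model = PUBLISHED_MODEL[subscale]
            sign = 1 if model.orientation is Orientation.HIGHER_BETTER else -1
            for edu in (2, 8, 13, 18):
                prev = None
                for age in range(20, 95, 5):
                    adj = adjust_score(
                        0.0, record(age=age, education=edu), PUBLISHED_MODEL, subscale
                    )
                    if prev is not None:
                        assert sign * (adj - prev) >= 0, (subscale, age, edu)
                    prev = adj


def _normal_equations_oracle(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Closed-form OLS solve, independent of statsmodels."""
    Xd = np.column_stack([np.ones(len(X)), X])
    return np.linalg.solve(Xd.T @ Xd, Xd.T @ y)


class TestFitNormativeModel:
    def _noise_cohort(self, seed, n=500):
        rng = np.random.default_rng(seed)
        recs = []
        for i in range(n):
            recs.append(
                SubjectRecord(
                    f"n{i}",
                    age=int(rng.integers(18, 92)),
                    sex="M" if rng.random() < 0.45 else "F",
                    education=int(rng.integers(2, 21)),
                    scores={s.value: float(rng.normal(10, 3)) for s in Subscale},
                )
            )
        return recs

    def test_null_cohort_retains_nothing_most_seeds(self):
        clean = 0
        for seed in range(25):
            model = fit_normative_model(
                self._noise_cohort(seed), Subscale.FREE_RECALL
            )
            if not model.terms:
                clean += 1
        # each covariate is falsely significant ~5% of the time
        assert clean >= 18

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        n = 200
        recs = []
        for i in range(n):
            age = int(rng.integers(18, 92))
            edu = int(rng.integers(2, 21))
            sex = "M" if rng.random() < 0.5 else "F"
            z = math.log10(100 - age)
            w = math.sqrt(edu)
            y = 3.0 + 5.0 * z + 1.0 * w + rng.normal(0, 0.5)
            recs.append(
                SubjectRecord(
                    f"o{i}", age, sex, edu, {Subscale.FREE_RECALL.value: y}
                )
            )
        model = fit_normative_model(recs, Subscale.FREE_RECALL)
        retained = {t.covariate: t.coefficient for t in model.terms}
        assert set(retained) == {"age", "education"}
        X = np.array(
            [
                [math.log10(100 - r.age), math.sqrt(r.education)]
                for r in recs
            ]
        )
        y = np.array([r.scores[Subscale.FREE_RECALL.value] for r in recs])
        beta = _normal_equations_oracle(X, y)
        assert retained["age"] == pytest.approx(beta[1], abs=1e-8)
        assert retained["education"] == pytest.approx(beta[2], abs=1e-8)

    def test_single_sex_cohort_is_rank_deficient(self):
        recs = self._noise_cohort(0)
        for r in recs:
            r.sex = "F"
        with pytest.raises(FrtError, match="sex"):
            fit_normative_model(recs, Subscale.FREE_RECALL)

    def test_too_small_cohort(self):
        with pytest.raises(FrtError, match="too small"):
            fit_normative_model(self._noise_cohort(0, n=10), Subscale.FREE_RECALL)

    def test_centering_constants_are_cohort_means(self, cohort_5000):
        model = fit_normative_model(cohort_5000, Subscale.FREE_RECALL)
        z = np.mean([math.log10(100 - r.age) for r in cohort_5000])
        centers = {t.covariate: t.center for t in model.terms}
        assert centers["age"] == pytest.approx(z, abs=1e-12)

    def test_printed_centering_constants_consistent_with_cohort(self, cohort_5000):
        """Soft check: printed constants are rounded cohort means."""
        z = np.mean([math.log10(100 - r.age) for r in cohort_5000])
        w = np.mean([math.sqrt(r.education) for r in cohort_5000])
        male = np.mean([r.sex == "M" for r in cohort_5000])
        assert z == pytest.approx(1.69, abs=0.02)
        assert w == pytest.approx(3.54, abs=0.02)
        assert male == pytest.approx(0.42, abs=0.02)


@pytest.fixture(scope="module")
def continuous_cohort():
    # plain Gaussian noise: the latent factors exist only to shape the
    # cross-correlations of the realistic cohort and are not part of the
    # linear generating model whose coefficients we recover here.
    cfg = CohortConfig(
        n=5000,
        seed=1,
        demographic_source="uniform",
        discretize=False,
        latent_loadings={s: (0.0, 0.0) for s in CohortConfig().latent_loadings},
    )
    return generate_cohort(cfg)


class TestParameterRecovery:
    @pytest.mark.parametrize(
        "subscale,expected",
        [
            (Subscale.FREE_RECALL, {"age": 10.23, "education": 2.317}),
            (Subscale.FAILED_RECOGNITION, {"age": -3.099, "sex": 0.601}),
            (Subscale.SEMANTIC_FM, {"age": -3.553}),
            (Subscale.NON_SEMANTIC_FM, {"age": -1.19, "education": -0.261}),
        ],
    )
    def test_generating_coefficients_recovered(
        self, continuous_cohort, subscale, expected
    ):
        model = fit_normative_model(continuous_cohort, subscale)
        got = {t.covariate: t.coefficient for t in model.terms}
        for cov, value in expected.items():
            assert cov in got, f"{subscale}: {cov} not retained"
            assert got[cov] == pytest.approx(value, rel=0.05)

    def test_fit_adjust_round_trip_decorrelates(self, continuous_cohort):
        model_fr = fit_normative_model(continuous_cohort, Subscale.FREE_RECALL)
        wrapped = NormativeModel(models={Subscale.FREE_RECALL: model_fr})
        adjusted = np.array(
            [
                adjust_score(
                    r.scores[Subscale.FREE_RECALL.value],
                    r,
                    wrapped,
                    Subscale.FREE_RECALL,
                )
                for r in continuous_cohort
            ]
        )
        z = np.array([math.log10(100 - r.age) for r in continuous_cohort])
        w = np.array([math.sqrt(r.education) for r in continuous_cohort])
        assert abs(np.corrcoef(adjusted, z)[0, 1]) < 0.02
        assert abs(np.corrcoef(adjusted, w)[0, 1]) < 0.02


class TestInternalCorrelations:
    def test_duplicated_columns(self):
        frame = pd.DataFrame(
            {
                s.value: np.arange(10.0)
                for s in Subscale
            }
        )
        r, p = internal_correlations(frame)
        assert r.loc["free_recall", "recognition"] == pytest.approx(1.0)

    def test_total_equals_semantic_in_limit(self):
        rng = np.random.default_rng(1)
        sem = rng.normal(4, 2, 500)
        frame = pd.DataFrame(
            {
                "free_recall": rng.normal(17, 5, 500),
                "recognition": rng.normal(29, 3, 500),
                "failed_recognition": rng.normal(2, 2, 500),
                "semantic_fm": sem,
                "non_semantic_fm": np.zeros(500),
                "total_fm": sem,  # var(non_semantic) -> 0
            }
        )
        r, _ = internal_correlations(frame)
        assert r.loc["semantic_fm", "total_fm"] == pytest.approx(1.0)

    def test_zero_variance_flagged_as_nan(self):
        frame = pd.DataFrame(
            {s.value: np.arange(10.0) for s in Subscale}
        )
        frame["non_semantic_fm"] = 0.0
        r, p = internal_correlations(frame)
        assert np.isnan(r.loc["non_semantic_fm", "free_recall"])
        assert r.loc["free_recall", "recognition"] == pytest.approx(1.0)

    def test_requires_three_subjects(self):
        frame = pd.DataFrame({s.value: [1.0, 2.0] for s in Subscale})
        with pytest.raises(FrtError, match="at least 3"):
            internal_correlations(frame)

    def test_published_sem_total_correlation(self, cohort_5000):
        r, _ = internal_correlations(
            pd.DataFrame([{k: v for k, v in rec.scores.items()} for rec in cohort_5000])
        )
        assert r.loc["semantic_fm", "total_fm"] == pytest.approx(0.963, abs=0.02)


class TestSerialization:
    def test_round_trip(self):
        payload = PUBLISHED_MODEL.to_dict()
        rebuilt = NormativeModel.from_dict(payload)
        for sub in Subscale:
            assert rebuilt[sub].terms == PUBLISHED_MODEL[sub].terms
            assert rebuilt[sub].orientation == PUBLISHED_MODEL[sub].orientation

    def test_published_coefficients_verbatim(self):
        terms = {t.covariate: t.coefficient for t in PUBLISHED_MODEL[Subscale.FREE_RECALL].terms}
        assert terms == {"age": 10.23, "education": 2.317}
        terms = {t.covariate: t.coefficient for t in PUBLISHED_MODEL[Subscale.TOTAL_FM].terms}
        assert terms == {"age": -3.837, "education": -0.698}
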