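"""Nonparametric one-sided tolerance limits and Equivalent-Score banding.

Adjusted scores from the normative sample are ranked worst -> best.  The
*outer* tolerance limit is the largest order statistic that, with the
requested confidence (default 95%), still lies below the worst 5% of the
population; the *inner* limit is its optimistic counterpart.  Both ranks
come from the binomial construction: with ``X ~ Binomial(n, 1 - coverage)``,

    outer rank = max { r : P(X <= r - 1) <= 1 - confidence }
    inner rank = min { r : P(X >= r)     <= 1 - confidence }

For n = 232 at 95/95 these are the 6th and 18th worst observations.

Equivalent Scores then band the adjusted-score axis into five ordinal
levels: 0 at or beyond the outer limit (abnormal), 1 up to the inner limit,
2 and 3 splitting the observations between the inner limit and the sample
median into two equal-count halves, 4 beyond the median.  Ties on a
boundary always fall into the lower (worse) band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateSampleError, InsufficientSampleError, SchemaError
from .normative import Orientation

__all__ = [
    "tolerance_rank",
    "min_n_for_outer_limit",
    "ToleranceLimits",
    "ESTable",
    "build_es_table",
    "assign_es",
    "cutoff_value",
]

ES_SCHEMA_VERSION = 1


def tolerance_rank(
    n: int,
    coverage: float = 0.95,
    confidence: float = 0.95,
    side: Literal["outer", "inner"] = "outer",
) -> int | None:
    """Order-statistic rank of a one-sided nonparametric tolerance limit.

    Ranks count from the worst observation (rank 1).  Returns ``None`` when
    no rank satisfies the construction (sample too small) — an explicit
    "no valid tolerance limit" signal rather than an exception.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not (0.0 < coverage < 1.0 and 0.0 < confidence < 1.0):
        raise ValueError("coverage and confidence must lie in (0, 1)")
    p = 1.0 - coverage
    alpha = 1.0 - confidence
    if side == "outer":
        # largest r with P(X <= r-1) <= alpha; CDF is increasing in r, so
        # search from below and keep the last admissible rank.
        best = None
        for r in range(1, n + 1):
            if stats.binom.cdf(r - 1, n, p) <= alpha:
                best = r
            else:
                break
        return best
    if side == "inner":
        # smallest r with P(X >= r) = 1 - CDF(r-1) <= alpha.
        for r in range(1, n + 1):
            if stats.binom.sf(r - 1, n, p) <= alpha:
                return r
        return None
    raise ValueError(f"side must be 'outer' or 'inner', got {side!r}")


def min_n_for_outer_limit(coverage: float = 0.95, confidence: float = 0.95) -> int:
    """Smallest n for which an outer tolerance limit exists (59 at 95/95)."""
    n = 1
    while tolerance_rank(n, coverage, confidence, "outer") is None:
        n += 1
    return n


@dataclass(frozen=True)
class ToleranceLimits:
    n: int
    coverage: float
    confidence: float
    outer_rank: int
    inner_rank: int
    outer_value: float  # on the original scale
    inner_value: float
    median_value: float


@dataclass
class ESTable:
    """Equivalent-Score conversion table for one subscale.

    Boundaries ``b0 < b1 <= b2 <= b3`` live on the *oriented* axis (larger =
    better, i.e. the negated score for higher_worse scales).  ``assign_es``
    maps any real score to a band; ``cutoff`` reports b0 back on the
    original scale together with the direction of abnormality.
    """

    subscale: str
    orientation: Orientation
    n: int
    coverage: float
    confidence: float
    limits: ToleranceLimits
    b0: float
    b1: float
    b2: float
    b3: float

    def oriented(self, score: float) -> float:
        if self.orientation is Orientation.HIGHER_WORSE:
            return -float(score)
        return float(score)

    def to_dict(self) -> dict:
        return {
            "schema_version": ES_SCHEMA_VERSION,
            "kind": "es_table",
            "subscale": self.subscale,
            "orientation": self.orientation.value,
            "n": self.n,
            "coverage": self.coverage,
            "confidence": self.confidence,
            "outer_rank": self.limits.outer_rank,
            "inner_rank": self.limits.inner_rank,
            "outer_value": self.limits.outer_value,
            "inner_value": self.limits.inner_value,
            "median_value": self.limits.median_value,
            "boundaries_oriented": [self.b0, self.b1, self.b2, self.b3],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ESTable":
        if payload.get("kind") != "es_table":
            raise SchemaError("artifact is not an es_table document")
        if payload.get("schema_version") != ES_SCHEMA_VERSION:
            raise SchemaError(
                f"unsupported es_table schema_version {payload.get('schema_version')!r}"
            )
        b0, b1, b2, b3 = (float(b) for b in payload["boundaries_oriented"])
        limits = ToleranceLimits(
            n=int(payload["n"]),
            coverage=float(payload["coverage"]),
            confidence=float(payload["confidence"]),
            outer_rank=int(payload["outer_rank"]),
            inner_rank=int(payload["inner_rank"]),
            outer_value=float(payload["outer_value"]),
            inner_value=float(payload["inner_value"]),
            median_value=float(payload["median_value"]),
        )
        return cls(
            subscale=payload["subscale"],
            orientation=Orientation(payload["orientation"]),
            n=limits.n,
            coverage=limits.coverage,
            confidence=limits.confidence,
            limits=limits,
            b0=b0,
            b1=b1,
            b2=b2,
            b3=b3,
        )


def build_es_table(
    adjusted: Sequence[float],
    orientation: Orientation,
    subscale: str = "",
    coverage: float = 0.95,
    confidence: float = 0.95,
) -> ESTable:
    """Build the five-band Equivalent-Score table from a normative sample."""
    scores = np.asarray(adjusted, dtype=float)
    n = scores.size
    outer = tolerance_rank(n, coverage, confidence, "outer")
    inner = tolerance_rank(n, coverage, confidence, "inner")
    if outer is None or inner is None:
        raise InsufficientSampleError(
            f"n={n} admits no {coverage:.0%}/{confidence:.0%} tolerance limit; "
            f"need n >= {min_n_for_outer_limit(coverage, confidence)}",
            minimum_n=min_n_for_outer_limit(coverage, confidence),
        )
    if np.ptp(scores) == 0.0:
        raise DegenerateSampleError(
            "all adjusted scores identical; ES bands undefined"
        )

    oriented = -scores if orientation is Orientation.HIGHER_WORSE else scores.copy()
    ranked = np.sort(oriented)  # worst -> best on the oriented axis
    b0 = float(ranked[outer - 1])
    b1 = float(ranked[inner - 1])
    b3 = float(np.median(ranked))
    # Observations ranked strictly between the inner limit and the median,
    # split into two equal-count halves; odd counts put the extra
    # observation (and hence the boundary value) in the lower band.
    mid = ranked[(ranked > b1) & (ranked <= b3)]
    if mid.size == 0:
        b2 = b1
    else:
        lower_size = int(np.ceil(mid.size / 2))
        b2 = float(mid[lower_size - 1])

    sign = -1.0 if orientation is Orientation.HIGHER_WORSE else 1.0
    limits = ToleranceLimits(
        n=n,
        coverage=coverage,
        confidence=confidence,
        outer_rank=outer,
        inner_rank=inner,
        outer_value=sign * b0,
        inner_value=sign * b1,
        median_value=sign * b3,
    )
    return ESTable(
        subscale=subscale,
        orientation=orientation,
        n=n,
        coverage=coverage,
        confidence=confidence,
        limits=limits,
        b0=b0,
        b1=b1,
        b2=b2,
        b3=b3,
    )


def assign_es(score: float, table: ESTable) -> int:
    """Equivalent Score (0-4) of an adjusted score.  Total on the reals."""
    x = table.oriented(score)
    if x <= table.b0:
        return 0
    if x <= table.b1:
        return 1
    if x <= table.b2:
        return 2
    if x <= table.b3:
        return 3
    return 4


def cutoff_value(table: ESTable) -> tuple[float, str]:
    """Abnormality cut-off: the outer tolerance limit on the original scale.

    Returns ``(value, direction)`` where direction is ``"<="`` for
    higher-is-better scales (abnormal at or below) and ``">="`` for
    higher-is-worse scales (abnormal at or above).
    """
    direction = "<=" if table.orientation is Orientation.HIGHER_BETTER else ">="
    return table.limits.outer_value, direction
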