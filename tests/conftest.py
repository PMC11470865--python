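"""Shared fixtures: sheet factories and reusable synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from frtnorm.cohort import CohortConfig, generate_cohort
from frtnorm.normative import PUBLISHED_MODEL
from frtnorm.scoring import (
    ITEMS_PER_LIST,
    N_LISTS,
    RECOGNITION_COMPOSITION,
    ItemClass,
    ListBlock,
    RecognitionItem,
    ResponseSheet,
)


def build_sheet(
    subject_id: str = "s1",
    endorse=lambda item_class, i: item_class is ItemClass.OLD,
    hits: int = ITEMS_PER_LIST,
) -> ResponseSheet:
    """Construct a structurally valid sheet; ``endorse(cls, index)`` decides
    each recognition response."""
    lists = []
    for _ in range(N_LISTS):
        items = []
        i = 0
        for cls, count in RECOGNITION_COMPOSITION.items():
            for _ in range(count):
                items.append(RecognitionItem(cls, bool(endorse(cls, i))))
                i += 1
        lists.append(ListBlock(free_recall_hits=hits, items=items))
    return ResponseSheet(subject_id, lists)


def random_sheet(rng: np.random.Generator, p: float = 0.5) -> ResponseSheet:
    hits = int(rng.integers(0, ITEMS_PER_LIST + 1))
    return build_sheet(
        subject_id=f"r{rng.integers(1e9)}",
        endorse=lambda cls, i: rng.random() < p,
        hits=hits,
    )


@pytest.fixture
def make_sheet():
    return build_sheet


@pytest.fixture
def make_random_sheet():
    return random_sheet


@pytest.fixture(scope="session")
def published_model():
    return PUBLISHED_MODEL


@pytest.fixture(scope="session")
def cohort_5000():
    """Default calibrated cohort (discretized, table demographics)."""
    return generate_cohort(CohortConfig(n=5000, seed=20240617))


@pytest.fixture(scope="session")
def cohort_232():
    return generate_cohort(CohortConfig(n=232, seed=99))
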