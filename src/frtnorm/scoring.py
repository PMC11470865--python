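"""Item-level scoring of false-recognition test response sheets.

The test presents three encoding lists (one per emotional valence).  After
free recall of each list, a 12-item recognition block follows containing the
6 studied ("old") words plus 6 new words: 1 critical lure, 2 strong semantic
associates and 3 unrelated words.  Words themselves are not modelled here;
items are abstract slots tagged with their class.

Six subscores are produced per subject:

================  =====  ==========================================
subscore          range  definition
================  =====  ==========================================
free_recall       0-36   correct productions summed over lists
recognition       0-36   old items endorsed + new items rejected
failed_recognition 0-18  old items not endorsed (misses)
semantic_fm       0-9    lures + semantic associates endorsed
non_semantic_fm   0-9    unrelated items endorsed
total_fm          0-18   semantic_fm + non_semantic_fm
================  =====  ==========================================

Two structural identities hold for every valid sheet and are enforced:
``total_fm == semantic_fm + non_semantic_fm`` and
``recognition + failed_recognition + total_fm == 36``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import SchemaError, SheetValidationError

__all__ = [
    "ItemClass",
    "RECOGNITION_COMPOSITION",
    "RecognitionItem",
    "ListBlock",
    "ResponseSheet",
    "ScoreSet",
    "score_sheet",
    "sheets_from_frame",
    "read_sheet_csv",
    "scores_to_frame",
]

N_LISTS = 3
ITEMS_PER_LIST = 12


class ItemClass(str, enum.Enum):
    """Class of a recognition item."""

    OLD = "OLD"
    LURE = "LURE"
    SEMANTIC_ASSOCIATE = "SEMANTIC_ASSOCIATE"
    UNRELATED = "UNRELATED"


#: Required composition of every 12-item recognition block.
RECOGNITION_COMPOSITION = {
    ItemClass.OLD: 6,
    ItemClass.LURE: 1,
    ItemClass.SEMANTIC_ASSOCIATE: 2,
    ItemClass.UNRELATED: 3,
}

#: Item classes counting toward the semantic false-memory score.
_SEMANTIC_NEW = frozenset({ItemClass.LURE, ItemClass.SEMANTIC_ASSOCIATE})


@dataclass(frozen=True)
class RecognitionItem:
    item_class: ItemClass
    endorsed: bool


@dataclass
class ListBlock:
    """One encoding list: its free-recall outcome and recognition block.

    ``free_recall_intrusions`` is carried for completeness but enters no
    subscore.
    """

    free_recall_hits: int
    items: Sequence[RecognitionItem]
    free_recall_intrusions: int = 0


@dataclass
class ResponseSheet:
    subject_id: str
    lists: Sequence[ListBlock] = field(default_factory=list)

    def validate(self) -> None:
        """Raise :class:`SheetValidationError` naming the violated invariant."""
        if len(self.lists) != N_LISTS:
            raise SheetValidationError(
                f"sheet {self.subject_id!r}: expected {N_LISTS} lists, "
                f"found {len(self.lists)}"
            )
        for i, block in enumerate(self.lists, start=1):
            if not 0 <= block.free_recall_hits <= ITEMS_PER_LIST:
                raise SheetValidationError(
                    f"sheet {self.subject_id!r} list {i}: free_recall_hits "
                    f"{block.free_recall_hits} outside [0, {ITEMS_PER_LIST}]"
                )
            if len(block.items) != ITEMS_PER_LIST:
                raise SheetValidationError(
                    f"sheet {self.subject_id!r} list {i}: expected "
                    f"{ITEMS_PER_LIST} recognition items, found {len(block.items)}"
                )
            counts: dict[ItemClass, int] = {c: 0 for c in ItemClass}
            for item in block.items:
                counts[item.item_class] += 1
            if counts != RECOGNITION_COMPOSITION:
                got = {c.value: n for c, n in counts.items()}
                want = {c.value: n for c, n in RECOGNITION_COMPOSITION.items()}
                raise SheetValidationError(
                    f"sheet {self.subject_id!r} list {i}: recognition block "
                    f"composition {got} != required {want}"
                )


@dataclass(frozen=True)
class ScoreSet:
    """The six raw subscores of one subject."""

    free_recall: int
    recognition: int
    failed_recognition: int
    semantic_fm: int
    non_semantic_fm: int
    total_fm: int

    _RANGES = {
        "free_recall": (0, 36),
        "recognition": (0, 36),
        "failed_recognition": (0, 18),
        "semantic_fm": (0, 9),
        "non_semantic_fm": (0, 9),
        "total_fm": (0, 18),
    }

    def __post_init__(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise SheetValidationError(f"{name}={v} outside [{lo}, {hi}]")
        if self.total_fm != self.semantic_fm + self.non_semantic_fm:
            raise SheetValidationError(
                "total_fm != semantic_fm + non_semantic_fm "
                f"({self.total_fm} != {self.semantic_fm} + {self.non_semantic_fm})"
            )
        if self.recognition + self.failed_recognition + self.total_fm != 36:
            raise SheetValidationError(
                "recognition + failed_recognition + total_fm != 36 "
                f"({self.recognition} + {self.failed_recognition} + {self.total_fm})"
            )

    def as_dict(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in self._RANGES}


def score_sheet(sheet: ResponseSheet) -> ScoreSet:
    """Score one validated response sheet.

    Recognition counts hits *and* correct rejections (range 0-36 over the
    3 x 12 recognition items), which is what makes
    ``recognition + failed_recognition + total_fm = 36`` an identity.
    """
    sheet.validate()
    free_recall = 0
    hits = misses = semantic = non_semantic = correct_rejections = 0
    for block in sheet.lists:
        free_recall += block.free_recall_hits
        for item in block.items:
            if item.item_class is ItemClass.OLD:
                if item.endorsed:
                    hits += 1
                else:
                    misses += 1
            elif item.item_class in _SEMANTIC_NEW:
                if item.endorsed:
                    semantic += 1
                else:
                    correct_rejections += 1
            else:  # UNRELATED
                if item.endorsed:
                    non_semantic += 1
                else:
                    correct_rejections += 1
    return ScoreSet(
        free_recall=free_recall,
        recognition=hits + correct_rejections,
        failed_recognition=misses,
        semantic_fm=semantic,
        non_semantic_fm=non_semantic,
        total_fm=semantic + non_semantic,
    )


# ---------------------------------------------------------------------------
# CSV dialect
#
# One row per recognition item:
#     subject_id, list_index (1-3), item_index (1-12), item_class, value (0/1)
# plus one row per list with item_class=FREE_RECALL (value = hits 0-12) and
# optionally item_class=FREE_RECALL_INTRUSIONS (value = count, ignored by
# scoring).  item_index is left empty on the per-list rows.
# ---------------------------------------------------------------------------

SHEET_COLUMNS = ["subject_id", "list_index", "item_index", "item_class", "value"]

_FREE_RECALL = "FREE_RECALL"
_INTRUSIONS = "FREE_RECALL_INTRUSIONS"


def sheets_from_frame(frame: pd.DataFrame) -> list[ResponseSheet]:
    """Assemble :class:`ResponseSheet` objects from a sheet-dialect frame.

    Sheets are returned in order of first appearance.  Structural validation
    is *not* performed here; callers decide whether to validate per sheet
    (``run_score`` logs per-sheet failures without aborting the batch).
    """
    missing = [c for c in SHEET_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"sheet CSV missing columns: {missing}")

    sheets: list[ResponseSheet] = []
    for subject_id, group in frame.groupby("subject_id", sort=False):
        blocks: list[ListBlock] = []
        for list_index, rows in group.groupby("list_index", sort=True):
            items: list[RecognitionItem] = []
            hits = 0
            intrusions = 0
            recog = rows[~rows["item_class"].isin([_FREE_RECALL, _INTRUSIONS])]
            recog = recog.sort_values("item_index")
            for _, row in recog.iterrows():
                try:
                    cls = ItemClass(row["item_class"])
                except ValueError as exc:
                    raise SchemaError(
                        f"subject {subject_id!r} list {list_index}: unknown "
                        f"item_class {row['item_class']!r}"
                    ) from exc
                items.append(RecognitionItem(cls, bool(int(row["value"]))))
            fr = rows[rows["item_class"] == _FREE_RECALL]
            if len(fr) == 1:
                hits = int(fr["value"].iloc[0])
            elif len(fr) > 1:
                raise SchemaError(
                    f"subject {subject_id!r} list {list_index}: multiple "
                    f"{_FREE_RECALL} rows"
                )
            intr = rows[rows["item_class"] == _INTRUSIONS]
            if len(intr) == 1:
                intrusions = int(intr["value"].iloc[0])
            blocks.append(ListBlock(hits, items, intrusions))
        sheets.append(ResponseSheet(str(subject_id), blocks))
    return sheets


def read_sheet_csv(path) -> list[ResponseSheet]:
    frame = pd.read_csv(path)
    return sheets_from_frame(frame)


def scores_to_frame(scored: Iterable[tuple[str, ScoreSet]]) -> pd.DataFrame:
    """Tabulate (subject_id, ScoreSet) pairs in the cohort CSV dialect."""
    rows = [{"subject_id": sid, **s.as_dict()} for sid, s in scored]
    columns = ["subject_id", *ScoreSet._RANGES]
    return pd.DataFrame(rows, columns=columns)
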