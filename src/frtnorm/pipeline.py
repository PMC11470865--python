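"""Batch orchestration: scoring runs, norm fitting, evaluation reports.

Everything here is deterministic given its inputs; artifacts carry schema
versions and are written with sorted keys so identical runs are
byte-identical (run timestamps go to the log, never into artifacts).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .equivalent import (
    ESTable,
    build_es_table,
    cutoff_value,
    min_n_for_outer_limit,
    tolerance_rank,
)
from .errors import FrtError, InsufficientSampleError, SchemaError, SheetValidationError
from .grid import GRID_SUBSCALES, CorrectionGrid, build_grid
from .normative import (
    NormativeModel,
    Orientation,
    Subscale,
    SubjectRecord,
    adjust_score,
    fit_all_subscales,
    read_cohort_csv,
)
from .scoring import read_sheet_csv, score_sheet, scores_to_frame

__all__ = [
    "NormArtifacts",
    "run_score",
    "run_norms",
    "run_evaluate",
    "stratified_cutoffs",
    "write_artifacts",
    "read_artifacts",
]

logger = logging.getLogger("frtnorm")

ARTIFACTS_SCHEMA_VERSION = 1

#: Demographic strata whose raw-score cut-offs replace a correction grid.
STRATA = {
    Subscale.SEMANTIC_FM: (
        {"name": "age<60", "age": (18, 59), "education": None},
        {"name": "age>=60", "age": (60, 99), "education": None},
    ),
    Subscale.NON_SEMANTIC_FM: (
        {"name": "age<60", "age": (18, 59), "education": None},
        {"name": "age60-79_edu<=5", "age": (60, 79), "education": (0, 5)},
        {"name": "age60-79_edu>5", "age": (60, 79), "education": (6, 99)},
        {"name": "age>=80", "age": (80, 99), "education": None},
    ),
}


def run_score(sheet_csv, out_csv=None) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Score a batch of response sheets.

    Malformed sheets are logged and reported as ``(subject_id, reason)``
    rejections; the batch never aborts on a single bad sheet.
    """
    sheets = read_sheet_csv(sheet_csv)
    scored = []
    rejections: list[tuple[str, str]] = []
    for sheet in sheets:
        try:
            scored.append((sheet.subject_id, score_sheet(sheet)))
        except SheetValidationError as exc:
            logger.warning("rejected sheet %s: %s", sheet.subject_id, exc)
            rejections.append((sheet.subject_id, str(exc)))
    frame = scores_to_frame(scored)
    if out_csv is not None:
        frame.to_csv(out_csv, index=False)
    logger.info("scored %d sheets, rejected %d", len(scored), len(rejections))
    return frame, rejections


def stratified_cutoffs(
    cohort: Sequence[SubjectRecord],
    coverage: float = 0.95,
    confidence: float = 0.95,
) -> dict:
    """Raw-score cut-offs for the uncorrected subscales, by demographic
    stratum.

    Strata too small to admit an outer tolerance limit yield an explicit
    ``{"available": false}`` entry carrying the minimum n, not an error.
    """
    out: dict = {}
    for subscale, strata in STRATA.items():
        per_scale = []
        for stratum in strata:
            lo_a, hi_a = stratum["age"]
            member = [
                r
                for r in cohort
                if lo_a <= r.age <= hi_a
                and (
                    stratum["education"] is None
                    or stratum["education"][0] <= r.education <= stratum["education"][1]
                )
            ]
            n = len(member)
            rank = tolerance_rank(n, coverage, confidence, "outer") if n else None
            if rank is None:
                per_scale.append(
                    {
                        "stratum": stratum["name"],
                        "n": n,
                        "available": False,
                        "minimum_n": min_n_for_outer_limit(coverage, confidence),
                    }
                )
                continue
            raws = sorted(
                (r.scores[subscale.value] for r in member), reverse=True
            )  # worst (highest) first for the error scales
            per_scale.append(
                {
                    "stratum": stratum["name"],
                    "n": n,
                    "available": True,
                    "outer_rank": rank,
                    "cutoff": float(raws[rank - 1]),
                    "direction": ">=",
                }
            )
        out[subscale.value] = per_scale
    return out


@dataclass
class NormArtifacts:
    model: NormativeModel
    es_tables: dict[Subscale, ESTable]
    grids: dict[Subscale, CorrectionGrid]
    raw_cutoffs: dict
    meta: dict


def run_norms(
    cohort: Sequence[SubjectRecord] | str | Path,
    alpha: float = 0.05,
    coverage: float = 0.95,
    confidence: float = 0.95,
) -> NormArtifacts:
    """Fit all six subscale models, ES tables and correction grids."""
    if not isinstance(cohort, (list, tuple)):
        cohort = read_cohort_csv(cohort)
    n = len(cohort)
    minimum = min_n_for_outer_limit(coverage, confidence)
    if n < minimum:
        raise InsufficientSampleError(
            f"cohort n={n} below the minimum n={minimum} for a "
            f"{coverage:.0%}/{confidence:.0%} outer tolerance limit",
            minimum_n=minimum,
        )
    model = fit_all_subscales(cohort, alpha=alpha)
    es_tables: dict[Subscale, ESTable] = {}
    for sub in Subscale:
        adjusted = [
            adjust_score(rec.scores[sub.value], rec, model, sub) for rec in cohort
        ]
        es_tables[sub] = build_es_table(
            adjusted,
            model[sub].orientation,
            subscale=sub.value,
            coverage=coverage,
            confidence=confidence,
        )
    grids = {sub: build_grid(model, sub) for sub in GRID_SUBSCALES}
    raw_cutoffs = stratified_cutoffs(cohort, coverage, confidence)
    meta = {
        "schema_version": ARTIFACTS_SCHEMA_VERSION,
        "n": n,
        "alpha": alpha,
        "coverage": coverage,
        "confidence": confidence,
    }
    return NormArtifacts(model, es_tables, grids, raw_cutoffs, meta)


def write_artifacts(artifacts: NormArtifacts, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _dump_yaml(artifacts.model.to_dict(), out / "model.yaml")
    _dump_yaml(
        {
            "schema_version": ARTIFACTS_SCHEMA_VERSION,
            "kind": "es_table_set",
            "tables": {
                sub.value: t.to_dict() for sub, t in artifacts.es_tables.items()
            },
        },
        out / "es_tables.yaml",
    )
    _dump_yaml(
        {
            "schema_version": ARTIFACTS_SCHEMA_VERSION,
            "kind": "correction_grid_set",
            "grids": {sub.value: g.to_dict() for sub, g in artifacts.grids.items()},
        },
        out / "grids.yaml",
    )
    _dump_yaml(
        {
            "schema_version": ARTIFACTS_SCHEMA_VERSION,
            "kind": "raw_cutoffs",
            "cutoffs": artifacts.raw_cutoffs,
        },
        out / "raw_cutoffs.yaml",
    )
    _dump_yaml({"kind": "run_meta", **artifacts.meta}, out / "run_meta.yaml")
    for sub, grid in artifacts.grids.items():
        grid.to_frame().to_csv(out / f"grid_{sub.value}.csv", index_label="age_band")


def read_artifacts(in_dir) -> NormArtifacts:
    src = Path(in_dir)
    model = NormativeModel.from_dict(_load_yaml(src / "model.yaml"))
    es_doc = _load_yaml(src / "es_tables.yaml")
    if es_doc.get("kind") != "es_table_set":
        raise SchemaError("es_tables.yaml is not an es_table_set document")
    es_tables = {
        Subscale(name): ESTable.from_dict(doc)
        for name, doc in es_doc["tables"].items()
    }
    grid_doc = _load_yaml(src / "grids.yaml")
    if grid_doc.get("kind") != "correction_grid_set":
        raise SchemaError("grids.yaml is not a correction_grid_set document")
    grids = {
        Subscale(name): CorrectionGrid.from_dict(doc)
        for name, doc in grid_doc["grids"].items()
    }
    cut_doc = _load_yaml(src / "raw_cutoffs.yaml")
    meta = _load_yaml(src / "run_meta.yaml")
    return NormArtifacts(model, es_tables, grids, cut_doc.get("cutoffs", {}), meta)


def _pyify(obj):
    """Recursively convert numpy scalars/arrays to plain python types."""
    import numpy as np

    if isinstance(obj, Mapping):
        return {_pyify(k): _pyify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pyify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _dump_yaml(payload: Mapping, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_pyify(payload), fh, sort_keys=True, default_flow_style=False)


def _load_yaml(path: Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _stratum_cutoff(raw_cutoffs: dict, subscale: Subscale, record: SubjectRecord):
    for entry in raw_cutoffs.get(subscale.value, []):
        spec = next(
            s for s in STRATA[subscale] if s["name"] == entry["stratum"]
        )
        lo_a, hi_a = spec["age"]
        if not lo_a <= record.age <= hi_a:
            continue
        if spec["education"] is not None:
            lo_e, hi_e = spec["education"]
            if not lo_e <= record.education <= hi_e:
                continue
        return entry
    return None


def run_evaluate(
    subjects: Sequence[SubjectRecord] | str | Path,
    artifacts: NormArtifacts,
) -> pd.DataFrame:
    """Per-subject norms report: adjusted scores, ES levels, abnormality.

    The ``abnormal_*`` flag for the adjusted scales is "at or beyond the
    cut-off" and coincides with ES 0 by construction; the two uncorrected
    false-memory scales are flagged from their stratified raw cut-offs when
    the subject's stratum has one.
    """
    from .equivalent import assign_es

    if not isinstance(subjects, (list, tuple)):
        subjects = read_cohort_csv(subjects)
    rows = []
    for rec in subjects:
        row: dict = {
            "subject_id": rec.subject_id,
            "age": rec.age,
            "sex": rec.sex,
            "education": rec.education,
        }
        for sub in Subscale:
            raw = rec.scores[sub.value]
            adjusted = adjust_score(raw, rec, artifacts.model, sub)
            table = artifacts.es_tables[sub]
            es = assign_es(adjusted, table)
            cut, direction = cutoff_value(table)
            abnormal = adjusted <= cut if direction == "<=" else adjusted >= cut
            row[f"{sub.value}_raw"] = raw
            row[f"{sub.value}_correction"] = round(adjusted - raw, 2)
            row[f"{sub.value}_adjusted"] = round(adjusted, 2)
            row[f"{sub.value}_es"] = es
            row[f"{sub.value}_abnormal"] = bool(abnormal)
            if sub in STRATA:
                entry = _stratum_cutoff(artifacts.raw_cutoffs, sub, rec)
                if entry is not None and entry.get("available"):
                    row[f"{sub.value}_raw_cutoff"] = entry["cutoff"]
                    row[f"{sub.value}_abnormal_raw"] = bool(raw >= entry["cutoff"])
        rows.append(row)
    return pd.DataFrame(rows)
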