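"""CSV and JSON input/output for paired studies, cohorts and stage reports.

CSV dialect: comma-separated, UTF-8, header required, ``.`` decimal separator.
Paired-study schema: ``subject_id,age,sex,tat_f,ncit_<label>_f,...``; cohort
schema: a single ``temp_f`` column.  Reports are JSON with full-precision
values plus a ``rounded`` display view; the full-precision block is the one
downstream stages consume.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from .types import Cohort, PairedRecord, round_display

__all__ = [
    "read_paired_csv",
    "write_paired_csv",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_report",
    "read_report",
    "SchemaError",
]

_NCIT_COL = re.compile(r"^ncit_(?P<label>.+?)_f$")
_NCIT_REP_COL = re.compile(r"^ncit_(?P<label>.+?)_rep(?P<rep>\d+)_f$")

log = logging.getLogger("feverscreen")


class SchemaError(ValueError):
    """Input file lacks a required column or carries an unparseable cell."""


def _parse_float(value: Any, row: int, column: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SchemaError(
            f"malformed numeric value {value!r} at row {row}, column {column!r}"
        ) from None


def read_paired_csv(path: str | Path) -> list[PairedRecord]:
    """Read a paired-study CSV into one :class:`PairedRecord` per row.

    Requires ``subject_id``, ``tat_f`` and at least one ``ncit_<label>_f``
    column.  Optional ``age``/``sex`` columns become ``None``/``unreported``
    when blank.  Sequential replicate columns ``ncit_<label>_rep1_f``,
    ``ncit_<label>_rep2_f``, ... are averaged into one value per distance
    (with a log note); a plain ``ncit_<label>_f`` column takes precedence.
    """
    df = pd.read_csv(path, dtype=str)
    for required in ("subject_id", "tat_f"):
        if required not in df.columns:
            raise SchemaError(f"missing required column {required!r}")
    rep_cols: dict[str, list[str]] = {}
    for c in df.columns:
        m = _NCIT_REP_COL.match(c)
        if m:
            rep_cols.setdefault(m["label"], []).append(c)
    ncit_cols = {
        c: _NCIT_COL.match(c)["label"]
        for c in df.columns
        if _NCIT_COL.match(c) and not _NCIT_REP_COL.match(c)
    }
    rep_cols = {lab: cols for lab, cols in rep_cols.items() if lab not in ncit_cols.values()}
    if rep_cols:
        log.info(
            "averaging replicate NCIT columns per distance: %s",
            {lab: sorted(cols) for lab, cols in rep_cols.items()},
        )
    if not ncit_cols and not rep_cols:
        raise SchemaError("no ncit_<label>_f column found")

    records: list[PairedRecord] = []
    for i, row in df.iterrows():
        age = None
        if "age" in df.columns and pd.notna(row["age"]) and str(row["age"]).strip():
            age = int(_parse_float(row["age"], i, "age"))
        sex = "unreported"
        if "sex" in df.columns and pd.notna(row["sex"]) and str(row["sex"]).strip():
            sex = str(row["sex"]).strip()
        t_ncit = {
            label: _parse_float(row[col], i, col) for col, label in ncit_cols.items()
        }
        for label, cols in rep_cols.items():
            t_ncit[label] = float(
                np.mean([_parse_float(row[c], i, c) for c in sorted(cols)])
            )
        records.append(
            PairedRecord(
                subject_id=str(row["subject_id"]),
                t_ref=_parse_float(row["tat_f"], i, "tat_f"),
                t_ncit=t_ncit,
                age=age,
                sex=sex,
            )
        )
    return records


def write_paired_csv(records: Iterable[PairedRecord], path: str | Path) -> None:
    """Write records in the paired-study schema (full precision, repr floats)."""
    records = list(records)
    labels: list[str] = []
    for r in records:
        for label in r.t_ncit:
            if label not in labels:
                labels.append(label)
    rows = []
    for r in records:
        row: dict[str, Any] = {
            "subject_id": r.subject_id,
            "age": "" if r.age is None else r.age,
            "sex": r.sex,
            "tat_f": repr(r.t_ref),
        }
        for label in labels:
            row[f"ncit_{label}_f"] = (
                repr(r.t_ncit[label]) if label in r.t_ncit else ""
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort_csv(path: str | Path, source_scale: str = "tat",
                    febrile_cut: float = 100.0) -> Cohort:
    """Read a single-column ``temp_f`` cohort CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "temp_f" not in df.columns:
        raise SchemaError("cohort CSV must contain a temp_f column")
    temps = df["temp_f"].astype(float).to_numpy()
    if temps.size == 0:
        raise SchemaError("cohort CSV contains no data rows")
    return Cohort(temps=temps, source_scale=source_scale, febrile_cut=febrile_cut)


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    # default formatting is the shortest round-trip repr of each float
    pd.DataFrame({"temp_f": np.asarray(cohort.temps, dtype=float)}).to_csv(
        path, index=False
    )


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _rounded_view(obj: Any, decimals: int) -> Any:
    if isinstance(obj, dict):
        return {k: _rounded_view(v, decimals) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_rounded_view(v, decimals) for v in obj]
    if isinstance(obj, float):
        return round_display(obj, decimals)
    return obj


def write_report(results: Any, path: str | Path, *, seed: int | None = None,
                 config: Any = None, rounded_decimals: int = 1) -> dict:
    """Serialize a stage output to JSON with full-precision and rounded views.

    The full-precision block is authoritative: recomputing a downstream stage
    from it reproduces the pipeline bit for bit.  Returns the document.
    """
    body = _to_jsonable(results)
    doc = {
        "seed": seed,
        "config": _to_jsonable(config),
        "results": body,
        "rounded": _rounded_view(body, rounded_decimals),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, indent=2, allow_nan=True))
    return doc


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
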