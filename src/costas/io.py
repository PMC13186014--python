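"""Tabular patient input/output.

Patients arrive either as a CSV with one row per patient or as JSON (a
single object or a list of objects); column/field names are exactly the
:class:`~costas.records.PatientRecord` field names and units are fixed by
the record contract.  Invalid rows do not abort a batch: they are collected
as per-row errors alongside the validated records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import pandas as pd

from .records import PatientRecord, RecordValidationError, validate_record

__all__ = ["RowError", "read_patients", "write_patients"]


@dataclass(frozen=True)
class RowError:
    """A single rejected input row: position (1-based) and reason."""

    row: int
    message: str


def _rows_from_json(path: Path) -> list[dict]:
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, dict):
        data = [data]
    if not isinstance(data, list) or not all(isinstance(r, dict) for r in data):
        raise ValueError(f"{path}: expected a JSON object or list of objects")
    return data


def read_patients(
    path: Union[str, Path], fmt: str = "auto"
) -> tuple[list[PatientRecord], list[RowError]]:
    """Read and validate a patient file.

    Returns ``(records, row_errors)``; a malformed file raises, a merely
    invalid row is reported in ``row_errors`` with its 1-based position.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "csv":
        rows = pd.read_csv(path, float_precision="round_trip").to_dict(orient="records")
    elif fmt == "json":
        rows = _rows_from_json(path)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected csv or json)")

    records: list[PatientRecord] = []
    errors: list[RowError] = []
    for i, raw in enumerate(rows, start=1):
        try:
            records.append(validate_record(raw))
        except RecordValidationError as exc:
            errors.append(RowError(row=i, message=str(exc)))
    return records, errors


def write_patients(records: list[PatientRecord], path: Union[str, Path], fmt: str = "auto") -> None:
    """Write records to CSV or JSON, the inverse of :func:`read_patients`."""
    path = Path(path)
    if fmt == "auto":
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    dumped = [r.model_dump(mode="json", exclude_none=True) for r in records]
    if fmt == "csv":
        # shortest round-trip float rendering, so CSV <-> JSON is lossless
        pd.DataFrame(dumped).to_csv(path, index=False, float_format=lambda x: repr(float(x)))
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(dumped, fh, indent=2)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected csv or json)")
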