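"""CSV/JSON readers and writers.

Observation tables are plain CSV (comma separator, dot decimal, UTF-8) with
header ``peptide_id,glycoform,rt_min[,peak_index][,intensity][,replicate]``;
assignment tables use ``peptide_id,glycoform,rt_min[,peak_index]``.  Window
models are JSON with the schema of :class:`~glycowin.rrt_model.RRTWindowModel`
(entries keyed by glycoform code).  All read errors carry the 1-based file
row number.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, List, Optional, Union

from pydantic import ValidationError

from glycowin.filtering import AssignmentRecord
from glycowin.rrt_model import RRTWindowEntry, RRTWindowModel, RTObservation, round_minutes

__all__ = [
    "TableFormatError",
    "read_observations",
    "write_observations",
    "read_assignments",
    "write_assignments",
    "read_model",
    "write_model",
]

PathLike = Union[str, Path]

_OBS_REQUIRED = ["peptide_id", "glycoform", "rt_min"]
_OBS_OPTIONAL = ["peak_index", "intensity", "replicate"]


class TableFormatError(ValueError):
    """A CSV or JSON input that does not match the declared dialect."""


def _check_header(fieldnames: Optional[List[str]], required: List[str], path: PathLike) -> None:
    if fieldnames is None:
        raise TableFormatError(f"{path}: empty file, expected a header row")
    missing = [c for c in required if c not in fieldnames]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {', '.join(missing)}")


def _parse_float(value: str, column: str, row: int, path: PathLike) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise TableFormatError(f"{path}, row {row}: nonnumeric {column} {value!r}") from None


def _parse_int(value: str, column: str, row: int, path: PathLike) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise TableFormatError(f"{path}, row {row}: noninteger {column} {value!r}") from None


def read_observations(path: PathLike) -> List[RTObservation]:
    """Read an observation CSV into typed records.

    Rows are numbered from 1 (the header) so error messages point at the
    offending file line.  Extra columns are ignored.
    """
    out: List[RTObservation] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, _OBS_REQUIRED, path)
        for i, row in enumerate(reader, start=2):
            rt = _parse_float(row["rt_min"], "rt_min", i, path)
            peak = _parse_int(row["peak_index"], "peak_index", i, path) if row.get("peak_index") else 1
            rep = _parse_int(row["replicate"], "replicate", i, path) if row.get("replicate") else 1
            inten = (
                _parse_float(row["intensity"], "intensity", i, path)
                if row.get("intensity")
                else None
            )
            try:
                out.append(
                    RTObservation(
                        peptide_id=row["peptide_id"],
                        glycoform=row["glycoform"],
                        rt_min=rt,
                        peak_index=peak,
                        intensity=inten,
                        replicate=rep,
                    )
                )
            except ValueError as exc:
                raise TableFormatError(f"{path}, row {i}: {exc}") from None
    return out


def write_observations(observations: Iterable[RTObservation], path: PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_OBS_REQUIRED + _OBS_OPTIONAL)
        for o in observations:
            writer.writerow(
                [
                    o.peptide_id,
                    o.glycoform,
                    repr(o.rt_min),
                    o.peak_index,
                    "" if o.intensity is None else repr(o.intensity),
                    o.replicate,
                ]
            )


def read_assignments(path: PathLike) -> List[AssignmentRecord]:
    """Read a candidate-assignment CSV (peptide_id, glycoform, rt_min[, peak_index])."""
    out: List[AssignmentRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, _OBS_REQUIRED, path)
        for i, row in enumerate(reader, start=2):
            rt = _parse_float(row["rt_min"], "rt_min", i, path)
            peak = _parse_int(row["peak_index"], "peak_index", i, path) if row.get("peak_index") else 1
            inten = (
                _parse_float(row["intensity"], "intensity", i, path)
                if row.get("intensity")
                else None
            )
            try:
                out.append(
                    AssignmentRecord(
                        peptide_id=row["peptide_id"],
                        glycoform=row["glycoform"],
                        rt_min=rt,
                        peak_index=peak,
                        intensity=inten,
                    )
                )
            except ValueError as exc:
                raise TableFormatError(f"{path}, row {i}: {exc}") from None
    return out


def write_assignments(records: Iterable[AssignmentRecord], path: PathLike) -> None:
    """Write annotated assignments.

    Window endpoints appear twice: at the 0.1-min reporting precision
    (``window_lower``/``window_upper``) and at full precision, because
    verdicts are decided on the unrounded values.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "peptide_id",
                "glycoform",
                "rt_min",
                "peak_index",
                "window_lower",
                "window_upper",
                "window_lower_exact",
                "window_upper_exact",
                "verdict",
            ]
        )
        for r in records:
            if r.predicted is not None:
                lo, up = r.predicted.rounded()
                lo_x, up_x = repr(r.predicted.lower_min), repr(r.predicted.upper_min)
            else:
                lo = up = lo_x = up_x = ""
            writer.writerow(
                [r.peptide_id, r.glycoform, repr(r.rt_min), r.peak_index, lo, up, lo_x, up_x, r.verdict or ""]
            )


def read_model(path: PathLike) -> RRTWindowModel:
    """Load and schema-validate a window-model JSON file."""
    with open(path, encoding="utf-8") as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise TableFormatError(f"{path}: invalid JSON ({exc})") from None
    try:
        return RRTWindowModel.model_validate(raw)
    except ValidationError as exc:
        raise TableFormatError(f"{path}: invalid window model: {exc}") from None


def write_model(model: RRTWindowModel, path: PathLike) -> None:
    """Serialize a model to JSON; read_model(write_model(m)) == m."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model.model_dump(mode="json"), fh, indent=2)
        fh.write("\n")
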