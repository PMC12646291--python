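"""Cohort CSV and weight-table config file handling.

CSV dialect: comma separated, UTF-8, mandatory header with the canonical
column names, booleans serialised as 0/1, missing values as empty fields.
"""

from __future__ import annotations

import csv
import importlib.resources
from typing import Optional, Sequence

import yaml

from .errors import ConfigError, RecordValidationError
from .records import COHORT_COLUMNS, PatientRecord, Violation
from .score import WeightTable

_BOOL_FIELDS = {"hairy_back", "diabetes", "prior_recurrence", "lateral_pits",
                "prior_abscess", "recurrence", "wound_dehiscence", "postop_infection"}
_INT_FIELDS = {"age", "n_midline_pits", "hospital_stay_days", "drain_removal_day"}
_FLOAT_FIELDS = {"bmi", "distance_to_anus_cm", "operative_time_min"}
_OPTIONAL_FIELDS = {"recurrence", "wound_dehiscence", "postop_infection",
                    "operative_time_min", "hospital_stay_days", "drain_removal_day"}
_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


def _parse_cell(name: str, raw: str, row_num: int):
    raw = raw.strip() if raw is not None else ""
    if raw == "":
        if name in _OPTIONAL_FIELDS:
            return None
        raise RecordValidationError(
            [Violation(name, f"row {row_num}: required field is empty")])
    try:
        if name in _BOOL_FIELDS:
            low = raw.lower()
            if low in _TRUE:
                return True
            if low in _FALSE:
                return False
            raise ValueError(f"not a boolean: {raw!r}")
        if name in _INT_FIELDS:
            return int(float(raw)) if float(raw).is_integer() else float(raw)
        if name in _FLOAT_FIELDS:
            return float(raw)
    except ValueError as exc:
        raise RecordValidationError(
            [Violation(name, f"row {row_num}: {exc}")]) from exc
    return raw


def read_cohort_csv(path) -> list[PatientRecord]:
    """Read a cohort CSV; raises with row/field context on malformed cells."""
    records = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise RecordValidationError([Violation("<file>", "empty file, no header")])
        missing = [c for c in COHORT_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise RecordValidationError(
                [Violation(c, "missing column in header") for c in missing])
        for row_num, row in enumerate(reader, start=2):
            kwargs = {name: _parse_cell(name, row.get(name, ""), row_num)
                      for name in COHORT_COLUMNS}
            records.append(PatientRecord(**kwargs))
    if not records:
        raise RecordValidationError([Violation("<file>", "no data rows")])
    return records


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return format(value, "g")
    return str(value)


def write_cohort_csv(records: Sequence[PatientRecord], path,
                     extra_columns: Optional[dict] = None) -> None:
    """Write a cohort CSV (optionally with extra per-record columns appended)."""
    extra = extra_columns or {}
    header = list(COHORT_COLUMNS) + list(extra)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for i, rec in enumerate(records):
            row = [_format_cell(getattr(rec, c)) for c in COHORT_COLUMNS]
            row += [_format_cell(extra[name][i]) for name in extra]
            writer.writerow(row)


def load_weight_table(path=None) -> WeightTable:
    """Load a weight table from YAML; the packaged default when no path given."""
    if path is None:
        ref = importlib.resources.files("piloscore.data") / "weights_default.yaml"
        text = ref.read_text(encoding="utf-8")
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError("weight table config must be a mapping")
    return WeightTable.from_dict(data)


def save_weight_table(weights: WeightTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(weights.to_dict(), fh, sort_keys=False)
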