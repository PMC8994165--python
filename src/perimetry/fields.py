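"""Visual-field records and their CSV serialization.

A :class:`VisualField` is one test: subject metadata, catch-trial rates
and one sensitivity in dB per grid location.  Files carry one row per
test with the header ``id,eye,date,age,duration,fpr,fnr,fl,grid,l1..lN``
where the ``lk`` columns follow the grid's stable location order.
Sensitivities are serialized with two decimals (missing = empty cell) and
dates as ISO 8601, so write -> read round trips are lossless.
"""

from __future__ import annotations

import csv
import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np

from .grids import GridRegistry, default_registry

__all__ = ["VisualField", "FieldError", "FieldParseError",
           "read_fields_csv", "write_fields_csv", "META_COLUMNS"]

META_COLUMNS = ("id", "eye", "date", "age", "duration", "fpr", "fnr", "fl",
                "grid")

#: dB values admitted on read: [floor - 5, ceiling] of the default 0-40
#: dynamic range.
DEFAULT_DB_RANGE = (0.0, 40.0)


class FieldError(ValueError):
    """Invalid visual-field record."""


class FieldParseError(FieldError):
    """CSV parse failure; the message names the offending row."""


@dataclass
class VisualField:
    """One visual-field test on a named grid.

    ``sensitivities`` holds one dB value per grid location in grid order;
    ``nan`` marks missing values (blind-spot locations are typically
    missing).
    """

    subject_id: str
    eye: str
    date: dt.date
    age: float
    duration: float
    fpr: float
    fnr: float
    fl: float
    grid_name: str
    sensitivities: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if self.eye not in ("OD", "OS"):
            raise FieldError(f"eye must be 'OD' or 'OS', got {self.eye!r}")
        for name in ("fpr", "fnr", "fl"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise FieldError(f"{name}={v} outside [0, 1]")
        self.sensitivities = np.asarray(self.sensitivities, dtype=float)

    def __eq__(self, other) -> bool:
        if not isinstance(other, VisualField):
            return NotImplemented
        same_meta = (
            self.subject_id == other.subject_id
            and self.eye == other.eye
            and self.date == other.date
            and self.age == other.age
            and self.duration == other.duration
            and self.fpr == other.fpr
            and self.fnr == other.fnr
            and self.fl == other.fl
            and self.grid_name == other.grid_name
        )
        if not same_meta:
            return False
        a, b = self.sensitivities, other.sensitivities
        if a.shape != b.shape:
            return False
        return bool(np.all((a == b) | (np.isnan(a) & np.isnan(b))))


def _fmt_db(v: float) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return ""
    return f"{v:.2f}"


def _fmt_num(v: float) -> str:
    return repr(float(v))


def write_fields_csv(fields, path) -> None:
    """Write visual-field records (all on one grid) to a CSV file."""
    fields = list(fields)
    if not fields:
        raise FieldError("no fields to write")
    grid_names = {f.grid_name for f in fields}
    if len(grid_names) > 1:
        raise FieldError(
            f"one file holds one grid; got {sorted(grid_names)}"
        )
    n = len(fields[0].sensitivities)
    header = list(META_COLUMNS) + [f"l{k}" for k in range(1, n + 1)]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for f in fields:
            if len(f.sensitivities) != n:
                raise FieldError(
                    f"field {f.subject_id!r} has {len(f.sensitivities)} "
                    f"sensitivities, expected {n}"
                )
            row = [
                f.subject_id, f.eye, f.date.isoformat(), _fmt_num(f.age),
                _fmt_num(f.duration), _fmt_num(f.fpr), _fmt_num(f.fnr),
                _fmt_num(f.fl), f.grid_name,
            ]
            row += [_fmt_db(v) for v in f.sensitivities]
            w.writerow(row)


def read_fields_csv(
    path,
    grid_registry: GridRegistry | None = None,
    db_range: tuple[float, float] = DEFAULT_DB_RANGE,
) -> list[VisualField]:
    """Read visual-field records, validating against the registered grid.

    Raises :class:`FieldParseError` naming the 1-based data row on any
    schema violation (wrong column count for the grid, unparseable date,
    rates outside [0, 1], sensitivities outside [floor-5, ceiling]).
    """
    reg = grid_registry if grid_registry is not None else default_registry
    lo, hi = db_range[0] - 5.0, db_range[1]
    fields: list[VisualField] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FieldParseError("empty file") from None
        if tuple(header[: len(META_COLUMNS)]) != META_COLUMNS:
            raise FieldParseError(
                f"header must start with {','.join(META_COLUMNS)}"
            )
        for rownum, row in enumerate(reader, start=1):
            if not row:
                continue
            try:
                (sid, eye, date_s, age_s, dur_s, fpr_s, fnr_s, fl_s,
                 grid_name) = row[: len(META_COLUMNS)]
            except ValueError:
                raise FieldParseError(f"row {rownum}: too few columns") from None
            if grid_name not in reg:
                raise FieldParseError(
                    f"row {rownum}: unknown grid {grid_name!r}"
                )
            grid = reg[grid_name]
            values = row[len(META_COLUMNS):]
            if len(values) != len(grid):
                raise FieldParseError(
                    f"row {rownum}: {len(values)} sensitivity columns for "
                    f"grid {grid_name!r} with {len(grid)} locations"
                )
            try:
                date = dt.date.fromisoformat(date_s)
            except ValueError:
                raise FieldParseError(
                    f"row {rownum}: unparseable date {date_s!r}"
                ) from None
            try:
                age = float(age_s)
                duration = float(dur_s)
                fpr, fnr, fl = float(fpr_s), float(fnr_s), float(fl_s)
            except ValueError as exc:
                raise FieldParseError(f"row {rownum}: {exc}") from None
            sens = np.full(len(grid), np.nan)
            for k, s in enumerate(values):
                if s == "":
                    continue
                try:
                    v = float(s)
                except ValueError:
                    raise FieldParseError(
                        f"row {rownum}: bad sensitivity {s!r} in column "
                        f"l{k + 1}"
                    ) from None
                if not (lo <= v <= hi):
                    raise FieldParseError(
                        f"row {rownum}: sensitivity {v} outside "
                        f"[{lo}, {hi}] in column l{k + 1}"
                    )
                sens[k] = v
            try:
                fields.append(
                    VisualField(sid, eye, date, age, duration, fpr, fnr,
                                fl, grid_name, sens)
                )
            except FieldError as exc:
                raise FieldParseError(f"row {rownum}: {exc}") from None
    return fields
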