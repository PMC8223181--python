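"""Reading, writing and validating scoring sheets, state metadata and index tables.

File dialects (all comma-delimited UTF-8, NA token is the literal ``NA``):

* scoring sheets, long format: ``state,category,metric,report_item,value``
  with ``report_item=ALL`` for category-wide cells.  Long format makes
  structurally-inapplicable cells unrepresentable instead of silently zero.
* state metadata: ``state,has_districts,confirmed_at_cutoff``
* external index: ``state,index_value`` (0-100 scale)
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .framework import CATEGORY_WIDE, FrameworkSpec, IndicatorId, enumerate_indicators

NA_TOKEN = "NA"

SHEET_HEADER = ["state", "category", "metric", "report_item", "value"]
META_HEADER = ["state", "has_districts", "confirmed_at_cutoff"]
INDEX_HEADER = ["state", "index_value"]


class SheetFormatError(ValueError):
    """Raised when a sheet/meta/index file is malformed or violates a domain."""


@dataclass(frozen=True)
class ScoreSheet:
    """One state's indicator values; ``None`` marks a state-inapplicable (NA) cell.

    Indicators absent from ``values`` are treated as NA by the scoring
    engine, so NA cells may be stored explicitly or simply omitted.
    """

    state_id: str
    values: Mapping[IndicatorId, Optional[int]]

    def value(self, indicator: IndicatorId) -> Optional[int]:
        return self.values.get(indicator)


@dataclass(frozen=True)
class StateMeta:
    state_id: str
    has_districts: bool = True
    confirmed_at_cutoff: int = 0


@dataclass(frozen=True)
class IndexRecord:
    state_id: str
    index_value: float


@dataclass(frozen=True)
class CohortTable:
    """A cohort of validated sheets plus per-state metadata."""

    sheets: tuple[ScoreSheet, ...]
    meta: Mapping[str, StateMeta] = field(default_factory=dict)

    def __post_init__(self):
        ids = [s.state_id for s in self.sheets]
        if len(ids) != len(set(ids)):
            raise SheetFormatError("duplicate state_id in cohort")

    def state_ids(self) -> list[str]:
        return [s.state_id for s in self.sheets]


def validate_sheet(spec: FrameworkSpec, sheet: ScoreSheet) -> list[str]:
    """Diagnostics for one sheet against the rubric (empty iff valid)."""
    diagnostics = []
    for ind, value in sheet.values.items():
        if ind not in spec.cells:
            diagnostics.append(f"{sheet.state_id}: unknown indicator {ind}")
            continue
        if value is not None and value not in spec.domain(ind):
            allowed = sorted(spec.domain(ind).allowed_values)
            diagnostics.append(
                f"{sheet.state_id}: value {value} outside domain {allowed} for cell {ind}"
            )
    return diagnostics


def read_cohort(path, spec: FrameworkSpec, meta: Mapping[str, StateMeta] | None = None) -> CohortTable:
    """Read a long-format scoring-sheet CSV into a validated cohort.

    The parse is total: every row is either consumed or reported with its
    line number.  Values outside the cell's domain and unknown indicators
    raise :class:`SheetFormatError`.
    """
    per_state: dict[str, dict[IndicatorId, Optional[int]]] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != SHEET_HEADER:
            raise SheetFormatError(
                f"{path}: expected header {','.join(SHEET_HEADER)!r}, got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) != 5:
                raise SheetFormatError(f"{path}:{lineno}: expected 5 fields, got {len(row)}")
            state, category, metric, item, raw = (cell.strip() for cell in row)
            if not state:
                raise SheetFormatError(f"{path}:{lineno}: empty state label")
            ind = IndicatorId(category, metric, item)
            if ind not in spec.cells:
                raise SheetFormatError(f"{path}:{lineno}: unknown indicator {ind}")
            if raw == NA_TOKEN:
                value: Optional[int] = None
            else:
                try:
                    value = int(raw)
                except ValueError:
                    raise SheetFormatError(
                        f"{path}:{lineno}: value {raw!r} is neither an integer nor {NA_TOKEN}"
                    ) from None
                if value not in spec.domain(ind):
                    allowed = sorted(spec.domain(ind).allowed_values)
                    raise SheetFormatError(
                        f"{path}:{lineno}: value {value} outside domain {allowed} for cell {ind}"
                    )
            cells = per_state.setdefault(state, {})
            if ind in cells:
                raise SheetFormatError(f"{path}:{lineno}: duplicate cell {ind} for state {state}")
            cells[ind] = value
    sheets = tuple(ScoreSheet(state_id=s, values=v) for s, v in per_state.items())
    return CohortTable(sheets=sheets, meta=dict(meta) if meta else {})


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort to the long-format CSV; round-trips with :func:`read_cohort`."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SHEET_HEADER)
        for sheet in cohort.sheets:
            for ind, value in sheet.values.items():
                token = NA_TOKEN if value is None else str(value)
                writer.writerow([sheet.state_id, ind.category, ind.metric, ind.item, token])


def full_sheet(spec: FrameworkSpec, state_id: str, fill) -> ScoreSheet:
    """Convenience: a sheet with every rubric cell set by ``fill(indicator)``."""
    return ScoreSheet(
        state_id=state_id,
        values={ind: fill(ind) for ind in enumerate_indicators(spec)},
    )


def read_meta(path) -> dict[str, StateMeta]:
    """Read the state-metadata CSV (``state,has_districts,confirmed_at_cutoff``)."""
    out: dict[str, StateMeta] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != META_HEADER:
            raise SheetFormatError(f"{path}: expected header {','.join(META_HEADER)!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 3:
                raise SheetFormatError(f"{path}:{lineno}: expected 3 fields")
            state, has_d, confirmed = (c.strip() for c in row)
            if state in out:
                raise SheetFormatError(f"{path}:{lineno}: duplicate state {state!r}")
            if has_d.lower() not in {"true", "false", "0", "1"}:
                raise SheetFormatError(f"{path}:{lineno}: has_districts must be boolean")
            n = int(confirmed)
            if n < 0:
                raise SheetFormatError(f"{path}:{lineno}: negative confirmed count")
            out[state] = StateMeta(
                state_id=state,
                has_districts=has_d.lower() in {"true", "1"},
                confirmed_at_cutoff=n,
            )
    return out


def write_meta(meta: Mapping[str, StateMeta], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(META_HEADER)
        for m in meta.values():
            writer.writerow([m.state_id, str(m.has_districts).lower(), m.confirmed_at_cutoff])


def apply_inclusion_filter(meta: Iterable[StateMeta], threshold: int = 10) -> list[str]:
    """States with at least ``threshold`` cumulative confirmed cases at cutoff.

    The cohort rule excludes states with *fewer than* ``threshold`` cases,
    so a count exactly at the threshold is included.  Input order is kept.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return [m.state_id for m in meta if m.confirmed_at_cutoff >= threshold]


def read_index_table(path) -> list[IndexRecord]:
    """Read the external-index CSV (``state,index_value``), values in [0, 100]."""
    records: list[IndexRecord] = []
    seen: set[str] = set()
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is not None and [h.strip() for h in header] != INDEX_HEADER:
            raise SheetFormatError(f"{path}: expected header {','.join(INDEX_HEADER)!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 2:
                raise SheetFormatError(f"{path}:{lineno}: expected 2 fields")
            state, raw = (c.strip() for c in row)
            if state in seen:
                raise SheetFormatError(f"{path}:{lineno}: duplicate state {state!r}")
            try:
                value = float(raw)
            except ValueError:
                raise SheetFormatError(f"{path}:{lineno}: non-numeric index value {raw!r}") from None
            if not 0.0 <= value <= 100.0:
                raise SheetFormatError(f"{path}:{lineno}: index value {value} outside [0, 100]")
            seen.add(state)
            records.append(IndexRecord(state_id=state, index_value=value))
    return records


def write_index_table(records: Iterable[IndexRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(INDEX_HEADER)
        for rec in records:
            writer.writerow([rec.state_id, repr(rec.index_value)])
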