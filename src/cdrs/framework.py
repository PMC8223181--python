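"""Declarative scoring rubric (the "framework").

The rubric is data, not code: a tree of categories -> metrics -> report
items, where every leaf cell carries a finite integer domain.  The default
framework models data-reporting quality for an infectious-disease outbreak
with 45 indicators across four categories:

* **availability** — are total / daily / historical numbers published for
  each report item (confirmed, deaths, recovered, quarantine, ICU)?
* **accessibility** — is the page easy to reach, is it in English, are
  trend graphics (total and daily) provided?
* **granularity** — are totals stratified by age, gender, comorbidities
  and districts?  Death comorbidity may score 2 when per-patient detail
  is published on top of the aggregate.
* **privacy** — a single cell with domain {-1, 1}: -1 when personally
  identifiable information is released, +1 otherwise.

A scoring engine built on :class:`FrameworkSpec` is generic over any rubric
of this shape; alternative rubrics load from YAML without code changes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

#: Canonical report items of the default framework.
REPORT_ITEMS: tuple[str, ...] = ("confirmed", "deaths", "recovered", "quarantine", "icu")

#: Canonical categories of the default framework, in rubric order.
CATEGORIES: tuple[str, ...] = ("availability", "accessibility", "granularity", "privacy")

#: Sentinel report item for category-wide cells (one cell spanning all items).
CATEGORY_WIDE: str = "ALL"


@dataclass(frozen=True, order=True)
class IndicatorId:
    """Identity of one scoreable cell: a (category, metric, report item) triple."""

    category: str
    metric: str
    item: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.category}/{self.metric}/{self.item}"


@dataclass(frozen=True)
class CellDomain:
    """Finite set of integer values a cell may take."""

    allowed_values: frozenset[int]

    @property
    def max(self) -> int:
        return max(self.allowed_values)

    @property
    def min(self) -> int:
        return min(self.allowed_values)

    def __contains__(self, value: int) -> bool:
        return value in self.allowed_values


@dataclass(frozen=True)
class FrameworkSpec:
    """A validated rubric: cell domains plus structurally inapplicable pairs.

    ``cells`` maps every scoreable :class:`IndicatorId` to its domain.
    ``structural_na`` lists (metric, item) pairs that are dashes in the
    rubric and are never scored for any cohort member.
    """

    cells: Mapping[IndicatorId, CellDomain]
    structural_na: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    @property
    def categories(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for ind in self.cells:
            seen.setdefault(ind.category, None)
        return tuple(seen)

    def domain(self, indicator: IndicatorId) -> CellDomain:
        try:
            return self.cells[indicator]
        except KeyError:
            raise KeyError(f"indicator {indicator} is not part of this framework") from None


class FrameworkError(ValueError):
    """Raised when a rubric file or object cannot be interpreted."""


def framework_from_mapping(tree: Mapping) -> FrameworkSpec:
    """Build a :class:`FrameworkSpec` from a categories->metrics->items tree."""
    cells: dict[IndicatorId, CellDomain] = {}
    try:
        categories = tree["categories"]
    except (KeyError, TypeError) as exc:
        raise FrameworkError("framework mapping lacks a 'categories' tree") from exc
    for category, metrics in categories.items():
        for metric, items in metrics.items():
            for item, values in items.items():
                ind = IndicatorId(str(category), str(metric), str(item))
                if not isinstance(values, (list, tuple)) or not values:
                    raise FrameworkError(f"cell {ind}: domain must be a non-empty list")
                try:
                    domain = CellDomain(frozenset(int(v) for v in values))
                except (TypeError, ValueError) as exc:
                    raise FrameworkError(f"cell {ind}: non-integer domain value") from exc
                cells[ind] = domain
    structural = frozenset(
        (str(metric), str(item)) for metric, item in tree.get("structural_na", [])
    )
    return FrameworkSpec(cells=cells, structural_na=structural)


def load_framework(path) -> FrameworkSpec:
    """Load a rubric from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        tree = yaml.safe_load(fh)
    return framework_from_mapping(tree)


_DEFAULT: FrameworkSpec | None = None


def default_framework() -> FrameworkSpec:
    """The packaged default rubric (45 indicators, four categories)."""
    global _DEFAULT
    if _DEFAULT is None:
        resource = importlib.resources.files("cdrs.data") / "default_framework.yaml"
        tree = yaml.safe_load(resource.read_text(encoding="utf-8"))
        _DEFAULT = framework_from_mapping(tree)
    return _DEFAULT


def enumerate_indicators(
    spec: FrameworkSpec, category: str | None = None
) -> list[IndicatorId]:
    """All indicators of ``spec`` in a deterministic (category, metric, item) order.

    Category order follows the rubric's declaration order; metrics and items
    likewise (insertion order of the mapping), which keeps the enumeration
    stable across runs and aligned with the printed rubric.
    """
    if category is not None and category not in spec.categories:
        raise KeyError(f"unknown category {category!r}")
    return [
        ind
        for ind in spec.cells
        if category is None or ind.category == category
    ]


def max_min_points(
    spec: FrameworkSpec, applicable: Iterable[IndicatorId]
) -> tuple[int, int]:
    """Sum of domain maxima and minima over the ``applicable`` cells."""
    max_points = 0
    min_points = 0
    for ind in applicable:
        domain = spec.domain(ind)
        max_points += domain.max
        min_points += domain.min
    return max_points, min_points


def validate_framework(spec: FrameworkSpec) -> list[str]:
    """Diagnostics for rubric invariants; empty list iff the rubric is sound.

    Checks: no empty cell domain, no (metric, item) pair claimed by two
    categories, and no structurally-NA pair that also carries a domain.
    """
    diagnostics: list[str] = []
    claimed: dict[tuple[str, str], str] = {}
    for ind, domain in spec.cells.items():
        if not domain.allowed_values:
            diagnostics.append(f"cell {ind}: empty domain")
        key = (ind.metric, ind.item)
        if key in claimed and claimed[key] != ind.category:
            diagnostics.append(
                f"cell {ind}: metric/item pair also assigned to category {claimed[key]!r}"
            )
        claimed.setdefault(key, ind.category)
        if (ind.metric, ind.item) in spec.structural_na:
            diagnostics.append(f"cell {ind}: marked structurally NA but has a domain")
    return diagnostics
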