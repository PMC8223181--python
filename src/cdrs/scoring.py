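"""Per-category and overall score computation with NA adjustment.

For a state *s* and category *c*, the categorical score is

    N(c, s) = T(c, s) / (M(c, s) - m(c, s))

where T is the sum of the state's cell values in the category and M, m are
the sums of the domain maxima and minima over the *applicable* (non-NA)
cells — the NA adjustment: an inapplicable cell contributes to neither the
total nor the bounds.  The overall score is

    CDRS(s) = sum_c T(c, s) / sum_c M(c, s)

over the same applicable cells, and lies in [0, 1] for every valid sheet.

Two NA rules are derived from content rather than trusted from input:

* the privacy cell is inapplicable when the state reports no data at all
  (every non-privacy cell 0 or NA);
* district-stratification cells should be NA for states without districts
  (checked by cohort validation against metadata, not silently rewritten).

With domains {0,1} everywhere except death-comorbidity {0,1,2} and privacy
{-1,1}, the normalized privacy score is +0.5 without a violation and -0.5
with one, and a fully perfect sheet scores exactly 1.

Arithmetic is exact: integer sums with a single rational division at the
end (``fractions.Fraction``), rendered as float only at the API surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Optional

from .framework import FrameworkSpec, IndicatorId, enumerate_indicators, max_min_points
from .io import CohortTable, ScoreSheet


class UndefinedScoreError(ValueError):
    """Raised when no cell of a sheet is applicable, so CDRS is undefined."""


@dataclass(frozen=True)
class CategoryScore:
    """Totals and bounds for one category; ``normalized`` is None when NA."""

    category: str
    total: int          # T: sum of applicable cell values
    max_points: int     # M: sum of applicable domain maxima
    min_points: int     # m: sum of applicable domain minima
    n_applicable: int

    @property
    def normalized(self) -> Optional[float]:
        if self.n_applicable == 0 or self.max_points == self.min_points:
            return None
        return float(Fraction(self.total, 1) / (self.max_points - self.min_points))


@dataclass(frozen=True)
class StateScore:
    state_id: str
    per_category: Mapping[str, CategoryScore]
    cdrs: float

    @property
    def cdrs_exact(self) -> Fraction:
        t = sum(c.total for c in self.per_category.values())
        m = sum(c.max_points for c in self.per_category.values())
        return Fraction(t, m)


def privacy_applicable(spec: FrameworkSpec, sheet: ScoreSheet) -> bool:
    """False iff the state reports nothing: every non-privacy cell is 0 or NA.

    When False the privacy cell is treated as NA in every downstream sum,
    whatever the input file says.
    """
    for ind in enumerate_indicators(spec):
        if ind.category == "privacy":
            continue
        value = sheet.value(ind)
        if value is not None and value >= 1:
            return True
    return False


def _applicable_cells(
    spec: FrameworkSpec, sheet: ScoreSheet, category: str
) -> list[tuple[IndicatorId, int]]:
    privacy_na = category == "privacy" and not privacy_applicable(spec, sheet)
    out = []
    for ind in enumerate_indicators(spec, category):
        value = sheet.value(ind)
        if value is None or privacy_na:
            continue
        out.append((ind, value))
    return out


def category_score(spec: FrameworkSpec, sheet: ScoreSheet, category: str) -> CategoryScore:
    """T, M, m and N for one category of one sheet, NA-adjusted."""
    cells = _applicable_cells(spec, sheet, category)
    max_points, min_points = max_min_points(spec, (ind for ind, _ in cells))
    return CategoryScore(
        category=category,
        total=sum(v for _, v in cells),
        max_points=max_points,
        min_points=min_points,
        n_applicable=len(cells),
    )


def cdrs(spec: FrameworkSpec, sheet: ScoreSheet) -> StateScore:
    """Overall score of one sheet: sum of category totals over sum of maxima."""
    per_category = {c: category_score(spec, sheet, c) for c in spec.categories}
    total = sum(cs.total for cs in per_category.values())
    max_points = sum(cs.max_points for cs in per_category.values())
    if max_points == 0:
        raise UndefinedScoreError(
            f"{sheet.state_id}: no applicable cell, overall score undefined"
        )
    return StateScore(
        state_id=sheet.state_id,
        per_category=per_category,
        cdrs=float(Fraction(total, max_points)),
    )


def score_cohort(
    spec: FrameworkSpec, cohort: CohortTable
) -> tuple[list[StateScore], list[tuple[str, str]]]:
    """Score every sheet, preserving order.

    Per-state failures (e.g. a sheet with no applicable cell) are collected
    as ``(state_id, message)`` pairs instead of aborting the cohort.
    """
    scores: list[StateScore] = []
    failures: list[tuple[str, str]] = []
    for sheet in cohort.sheets:
        try:
            scores.append(cdrs(spec, sheet))
        except UndefinedScoreError as exc:
            failures.append((sheet.state_id, str(exc)))
    return scores, failures


def validate_cohort(spec: FrameworkSpec, cohort: CohortTable) -> list[str]:
    """Cohort-level consistency warnings beyond per-sheet domain validation.

    * a privacy cell whose NA-ness contradicts the derived rule;
    * district cells not marked NA for a state whose metadata says it has
      no districts (and vice versa).
    """
    from .io import validate_sheet

    diagnostics: list[str] = []
    for sheet in cohort.sheets:
        diagnostics.extend(validate_sheet(spec, sheet))
        applicable = privacy_applicable(spec, sheet)
        for ind in enumerate_indicators(spec, "privacy") if "privacy" in spec.categories else []:
            value = sheet.value(ind)
            if value is None and applicable:
                diagnostics.append(
                    f"{sheet.state_id}: privacy marked NA but the state reports data"
                )
            if value is not None and not applicable:
                diagnostics.append(
                    f"{sheet.state_id}: privacy scored but the state reports no data"
                )
        meta = cohort.meta.get(sheet.state_id)
        if meta is not None and not meta.has_districts:
            for ind in enumerate_indicators(spec):
                if ind.metric == "districts" and sheet.value(ind) is not None:
                    diagnostics.append(
                        f"{sheet.state_id}: district cell {ind} scored but state has no districts"
                    )
    return diagnostics
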