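"""Cohort-level summaries and correlation with an external development index.

The five-number summary uses a configurable quantile convention (numpy's
``method`` names, default linear interpolation between order statistics).
Correlation reports the Pearson product-moment coefficient and Spearman's
rank coefficient (mid-ranks for ties), each with a two-sided p-value from
the t transform r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .framework import FrameworkSpec, IndicatorId, enumerate_indicators
from .io import CohortTable, IndexRecord
from .scoring import StateScore


@dataclass(frozen=True)
class CohortSummary:
    n: int
    five_number: tuple[float, float, float, float, float]
    ranking: tuple[str, ...]
    category_medians: Mapping[str, float]


@dataclass(frozen=True)
class ReportingCounts:
    counts: Mapping[IndicatorId, int]


@dataclass(frozen=True)
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_r: float
    spearman_p: float
    n_pairs: int


class CorrelationError(ValueError):
    """Too few matched pairs, or a variable with zero variance."""


def five_number_summary(
    values: Sequence[float], method: str = "linear"
) -> tuple[float, float, float, float, float]:
    """(min, Q1, median, Q3, max) under the given quantile convention."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("five_number_summary requires a non-empty list")
    q = np.quantile(arr, [0.0, 0.25, 0.5, 0.75, 1.0], method=method)
    return tuple(float(x) for x in q)


def rank_states(scores: Iterable[StateScore]) -> list[str]:
    """State ids in decreasing score order; ties broken alphabetically."""
    ordered = sorted(scores, key=lambda s: (-s.cdrs, s.state_id))
    return [s.state_id for s in ordered]


def summarize_cohort(scores: Sequence[StateScore], method: str = "linear") -> CohortSummary:
    """Five-number summary, ranking and per-category medians of a scored cohort."""
    if not scores:
        raise ValueError("cannot summarize an empty cohort")
    categories: dict[str, list[float]] = {}
    for s in scores:
        for c, cs in s.per_category.items():
            if cs.normalized is not None:
                categories.setdefault(c, []).append(cs.normalized)
    medians = {c: float(np.median(v)) for c, v in categories.items()}
    return CohortSummary(
        n=len(scores),
        five_number=five_number_summary([s.cdrs for s in scores], method=method),
        ranking=tuple(rank_states(scores)),
        category_medians=medians,
    )


def reporting_counts(spec: FrameworkSpec, cohort: CohortTable) -> ReportingCounts:
    """Per indicator, the number of states scoring at least 1 (NA and 0 excluded)."""
    counts = {ind: 0 for ind in enumerate_indicators(spec)}
    for sheet in cohort.sheets:
        for ind in counts:
            value = sheet.value(ind)
            if value is not None and value >= 1:
                counts[ind] += 1
    return ReportingCounts(counts=counts)


def _normalize_name(name: str) -> str:
    return " ".join(name.casefold().split())


def correlate(
    scores: Sequence[StateScore], index: Sequence[IndexRecord]
) -> CorrelationResult:
    """Pearson and Spearman correlation between scores and an external index.

    The two tables are inner-joined on case-folded, whitespace-normalized
    state names; at least 3 matched pairs are required.
    """
    by_state = {_normalize_name(r.state_id): r.index_value for r in index}
    xs, ys = [], []
    for s in scores:
        key = _normalize_name(s.state_id)
        if key in by_state:
            xs.append(s.cdrs)
            ys.append(by_state[key])
    n = len(xs)
    if n < 3:
        raise CorrelationError(f"only {n} matched state pairs; need at least 3")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CorrelationError("zero variance in scores or index values")
    pearson = sps.pearsonr(x, y)
    spearman = sps.spearmanr(x, y)
    return CorrelationResult(
        pearson_r=float(pearson.statistic),
        pearson_p=float(pearson.pvalue),
        spearman_r=float(spearman.statistic),
        spearman_p=float(spearman.pvalue),
        n_pairs=n,
    )


def permutation_spearman_p(
    scores: Sequence[float], index: Sequence[float], n_perm: int = 9999, seed: int = 0
) -> float:
    """Seeded two-sided permutation p-value for Spearman's rho (small cohorts)."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(index, dtype=float)
    observed = abs(sps.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        r = sps.spearmanr(x, rng.permutation(y)).statistic
        if abs(r) >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)
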