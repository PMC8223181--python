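"""Scoring engine: normalization values, NA rules, and oracle equivalence.

The independent oracle below recomputes every score by direct dictionary
iteration over the raw cells — no shared code path with the engine, which
goes through enumeration helpers and exact rational arithmetic.
"""

from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cdrs import (
    CellDomain,
    CohortTable,
    FrameworkSpec,
    IndicatorId,
    ScoreSheet,
    UndefinedScoreError,
    category_score,
    cdrs,
    full_sheet,
    privacy_applicable,
    score_cohort,
    validate_cohort,
)

# ---------------------------------------------------------------- oracle


def oracle_state_score(spec, sheet):
    """Brute-force T/M/m per category and overall score, straight off the dicts."""
    reports_data = any(
        v is not None and v >= 1
        for i, v in sheet.values.items()
        if i.category != "privacy"
    )
    per_cat = {}
    for cat in {i.category for i in spec.cells}:
        t = big = small = 0
        n = 0
        for ind, dom in spec.cells.items():
            if ind.category != cat:
                continue
            v = sheet.values.get(ind)
            if v is None:
                continue
            if cat == "privacy" and not reports_data:
                continue
            t += v
            big += max(dom.allowed_values)
            small += min(dom.allowed_values)
            n += 1
        per_cat[cat] = (t, big, small, n)
    total_t = sum(t for t, *_ in per_cat.values())
    total_m = sum(big for _, big, *_ in per_cat.values())
    overall = None if total_m == 0 else Fraction(total_t, total_m)
    return per_cat, overall


# ------------------------------------------------------- random rubrics

_items = st.sampled_from(["confirmed", "deaths", "recovered", "x"])


@st.composite
def small_frameworks(draw):
    # non-privacy domains are zero-based, as in any rubric of this shape:
    # 0 encodes "unreported", positive values encode reporting depth
    cells = {}
    n_cat = draw(st.integers(min_value=1, max_value=3))
    for c in range(n_cat):
        for m in range(draw(st.integers(min_value=1, max_value=3))):
            for item in draw(st.sets(_items, min_size=1, max_size=2)):
                extra = draw(st.sets(st.integers(min_value=1, max_value=3), max_size=2))
                cells[IndicatorId(f"cat{c}", f"metric{m}", item)] = CellDomain(
                    frozenset({0} | extra)
                )
    if draw(st.booleans()):
        cells[IndicatorId("privacy", "privacy", "ALL")] = CellDomain(frozenset({-1, 1}))
    return FrameworkSpec(cells=cells)


@st.composite
def framework_and_sheet(draw):
    spec = draw(small_frameworks())
    values = {
        ind: draw(st.one_of(st.none(), st.sampled_from(sorted(dom.allowed_values))))
        for ind, dom in spec.cells.items()
    }
    return spec, ScoreSheet(state_id="s", values=values)


# ----------------------------------------------------------------- tests


class TestNormalization:
    def test_privacy_plus_one_normalizes_to_half(self, spec, perfect_sheet):
        cs = category_score(spec, perfect_sheet, "privacy")
        assert (cs.total, cs.max_points, cs.min_points) == (1, 1, -1)
        assert cs.normalized == 0.5

    def test_privacy_violation_normalizes_to_minus_half(self, spec):
        sheet = full_sheet(
            spec, "leaky", lambda i: -1 if i.category == "privacy" else spec.domain(i).max
        )
        assert category_score(spec, sheet, "privacy").normalized == -0.5

    def test_perfect_sheet_scores_one(self, spec, perfect_sheet):
        score = cdrs(spec, perfect_sheet)
        assert score.cdrs == 1.0
        for cat in ("availability", "accessibility", "granularity"):
            assert score.per_category[cat].normalized == 1.0

    def test_full_availability_category(self, spec, perfect_sheet):
        cs = category_score(spec, perfect_sheet, "availability")
        assert (cs.total, cs.max_points, cs.min_points, cs.normalized) == (15, 15, 0, 1.0)

    def test_no_data_sheet_scores_zero_with_privacy_na(self, spec, nodata_sheet):
        score = cdrs(spec, nodata_sheet)
        assert score.cdrs == 0.0
        assert score.per_category["privacy"].normalized is None

    def test_violation_on_otherwise_perfect_sheet(self, spec):
        sheet = full_sheet(
            spec, "leaky", lambda i: -1 if i.category == "privacy" else spec.domain(i).max
        )
        assert cdrs(spec, sheet).cdrs_exact == Fraction(44, 46)

    def test_granularity_for_a_state_without_districts(self, spec):
        # 12 applicable cells once the 5 district cells are NA; death
        # comorbidity at 2 gives T = M = 13 and a perfect normalized score
        def fill(i):
            if i.metric == "districts":
                return None
            return spec.domain(i).max

        cs = category_score(spec, full_sheet(spec, "island", fill), "granularity")
        assert (cs.total, cs.max_points, cs.n_applicable) == (13, 13, 12)
        assert cs.normalized == 1.0

    def test_all_na_sheet_raises_undefined(self, spec):
        sheet = full_sheet(spec, "ghost", lambda i: None)
        with pytest.raises(UndefinedScoreError):
            cdrs(spec, sheet)


class TestPrivacyApplicability:
    def test_all_zero_sheet_makes_privacy_inapplicable(self, spec, nodata_sheet):
        assert not privacy_applicable(spec, nodata_sheet)

    def test_single_reported_cell_makes_privacy_applicable(self, spec):
        values = {IndicatorId("availability", "total", "confirmed"): 1}
        assert privacy_applicable(spec, ScoreSheet("s", values))

    def test_all_na_sheet_is_inapplicable(self, spec):
        sheet = full_sheet(spec, "ghost", lambda i: None)
        assert not privacy_applicable(spec, sheet)

    def test_stated_privacy_value_is_overridden_when_inapplicable(self, spec):
        # file says privacy=1 but the state reports nothing: derived NA wins
        sheet = full_sheet(spec, "s", lambda i: 1 if i.category == "privacy" else 0)
        score = cdrs(spec, sheet)
        assert score.per_category["privacy"].n_applicable == 0
        assert score.cdrs == 0.0
        cohort = CohortTable(sheets=(sheet,))
        assert any("reports no data" in d for d in validate_cohort(spec, cohort))


class TestOracleEquivalence:
    @given(framework_and_sheet())
    def test_engine_matches_brute_force(self, pair):
        spec, sheet = pair
        expected_cats, expected_overall = oracle_state_score(spec, sheet)
        if expected_overall is None:
            with pytest.raises(UndefinedScoreError):
                cdrs(spec, sheet)
            return
        score = cdrs(spec, sheet)
        assert score.cdrs_exact == expected_overall
        for cat, (t, big, small, n) in expected_cats.items():
            cs = score.per_category[cat]
            assert (cs.total, cs.max_points, cs.min_points, cs.n_applicable) == (t, big, small, n)

    @given(framework_and_sheet())
    def test_overall_score_is_bounded_for_nonnegative_rubrics(self, pair):
        spec, sheet = pair
        try:
            score = cdrs(spec, sheet)
        except UndefinedScoreError:
            return
        assert 0.0 <= score.cdrs <= 1.0
        for cat, cs in score.per_category.items():
            if cs.normalized is None:
                continue
            if cat == "privacy":
                assert cs.normalized in (-0.5, 0.5)
            else:
                assert 0.0 <= cs.normalized <= 1.0

    @given(framework_and_sheet(), st.randoms(use_true_random=False))
    def test_raising_one_cell_never_lowers_the_score(self, pair, rnd):
        spec, sheet = pair
        raisable = [
            (ind, v)
            for ind, v in sheet.values.items()
            if v is not None and any(w > v for w in spec.domain(ind).allowed_values)
        ]
        if not raisable:
            return
        ind, v = rnd.choice(raisable)
        higher = min(w for w in spec.domain(ind).allowed_values if w > v)
        bumped = ScoreSheet("s", {**sheet.values, ind: higher})

        def score_or_none(sh):
            try:
                return cdrs(spec, sh).cdrs
            except UndefinedScoreError:
                return None
        after = score_or_none(bumped)
        before = score_or_none(sheet)
        if after is None:
            # only an all-NA-but-privacy sheet stays undefined after a raise
            assert before is None
        else:
            assert after >= (before or 0.0) - 1e-12

    @given(framework_and_sheet(), st.randoms(use_true_random=False))
    def test_na_cell_equals_deleted_cell(self, pair, rnd):
        spec, sheet = pair
        ind = rnd.choice(sorted(spec.cells))
        as_na = ScoreSheet("s", {**sheet.values, ind: None})
        pruned_spec = FrameworkSpec(
            cells={k: v for k, v in spec.cells.items() if k != ind},
            structural_na=spec.structural_na,
        )
        pruned_sheet = ScoreSheet("s", {k: v for k, v in sheet.values.items() if k != ind})

        def result(s, sh):
            try:
                score = cdrs(s, sh)
            except UndefinedScoreError:
                return "undefined"
            return score.cdrs_exact

        assert result(spec, as_na) == result(pruned_spec, pruned_sheet)


class TestScoreCohort:
    def test_order_preserved_and_failures_collected(self, spec, perfect_sheet, nodata_sheet):
        ghost = full_sheet(spec, "ghost", lambda i: None)
        cohort = CohortTable(sheets=(perfect_sheet, ghost, nodata_sheet))
        scores, failures = score_cohort(spec, cohort)
        assert [s.state_id for s in scores] == ["perfect", "silent"]
        assert failures == [("ghost", failures[0][1])] and "ghost" in failures[0][1]

    def test_rescoring_is_deterministic(self, spec, perfect_sheet, nodata_sheet):
        cohort = CohortTable(sheets=(perfect_sheet, nodata_sheet))
        assert score_cohort(spec, cohort) == score_cohort(spec, cohort)

    def test_empty_cohort(self, spec):
        assert score_cohort(spec, CohortTable(sheets=())) == ([], [])
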