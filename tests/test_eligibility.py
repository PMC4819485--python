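import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from audioscreen import (
    Audiogram,
    BaselineKind,
    CANONICAL_GRID,
    InclusionCriteria,
    PatientRecord,
    Recommendation,
    difference_series,
    evaluate,
    grade,
    is_eligible,
    max_window,
    pure_tone_average,
    recruitment_rate,
    window_means,
)


def brute_force_max_window(series, grid, window_size):
    """Independent enumeration of every complete window and its mean."""
    best = None
    for i in range(len(grid) - window_size + 1):
        freqs = grid[i : i + window_size]
        if all(f in series for f in freqs):
            mean = sum(series[f] for f in freqs) / window_size
            if best is None or mean > best[1]:
                best = (tuple(freqs), mean)
    return best


class TestDifferenceSeries:
    def test_identical_audiograms_give_zero(self):
        ag = Audiogram({f: 40 for f in CANONICAL_GRID})
        assert all(v == 0 for v in difference_series(ag, ag).values())

    def test_uniform_offset(self):
        base = Audiogram({f: 20 for f in CANONICAL_GRID})
        acute = Audiogram({f: 50 for f in CANONICAL_GRID})
        assert all(v == 30 for v in difference_series(acute, base).values())

    def test_restricted_to_shared_frequencies(self):
        acute = Audiogram({0.5: 50, 1: 50, 2: 50})
        base = Audiogram({1: 10, 2: 10, 4: 10})
        assert set(difference_series(acute, base)) == {1.0, 2.0}

    def test_empty_intersection_is_empty_not_raised(self):
        assert difference_series(Audiogram({0.5: 50}), Audiogram({4: 10})) == {}


class TestWindowMeans:
    def test_constant_series_full_grid(self):
        series = {f: 25.0 for f in CANONICAL_GRID}
        windows = window_means(series, CANONICAL_GRID, 3)
        assert len(windows) == 7
        assert all(w.complete and w.mean_difference == 25.0 for w in windows)

    def test_single_complete_window_mean(self):
        # only 0.5/1/2 kHz present: the 0.5-2 window is the only complete one
        series = {0.5: 40.0, 1.0: 45.0, 2.0: 55.0}
        windows = window_means(series, CANONICAL_GRID, 3)
        complete = [w for w in windows if w.complete]
        assert len(complete) == 1
        assert complete[0].window == (0.5, 2.0)
        assert complete[0].mean_difference == pytest.approx(46.666666666666664)

    def test_windows_containing_missing_frequency_are_incomplete(self):
        series = {f: 10.0 for f in CANONICAL_GRID if f != 1.0}
        windows = window_means(series, CANONICAL_GRID, 3)
        for w in windows:
            assert w.complete == (1.0 not in w.frequencies)

    def test_oversized_window_yields_empty_list(self):
        assert window_means({1.0: 5.0}, CANONICAL_GRID, len(CANONICAL_GRID) + 1) == []

    def test_window_size_one_is_per_frequency(self):
        series = {0.5: 10.0, 4.0: 35.0}
        windows = window_means(series, CANONICAL_GRID, 1)
        by_freq = {w.frequencies[0]: w for w in windows}
        assert by_freq[4.0].mean_difference == 35.0
        assert not by_freq[8.0].complete


class TestMaxWindow:
    def test_argmax_of_complete_windows(self):
        series = dict(zip(CANONICAL_GRID, [10, 10, 40, 45, 55, 20, 10, 0, 0]))
        best = max_window(window_means(series, CANONICAL_GRID, 3))
        assert best.window == (0.5, 2.0)
        assert best.mean_difference == pytest.approx(140 / 3)

    def test_tie_breaks_to_lowest_first_frequency(self):
        series = {f: 30.0 for f in CANONICAL_GRID}
        best = max_window(window_means(series, CANONICAL_GRID, 3))
        assert best.window == (0.125, 0.5)

    def test_absent_when_no_complete_window(self):
        assert max_window(window_means({8.0: 50.0}, CANONICAL_GRID, 3)) is None

    @given(st.data())
    @settings(max_examples=300)
    def test_agrees_with_brute_force_enumeration(self, data):
        present = data.draw(
            st.lists(st.sampled_from(CANONICAL_GRID), unique=True, min_size=0, max_size=9)
        )
        series = {
            f: data.draw(st.floats(min_value=-130, max_value=130, allow_nan=False))
            for f in present
        }
        size = data.draw(st.integers(min_value=1, max_value=4))
        best = max_window(window_means(series, CANONICAL_GRID, size))
        expected = brute_force_max_window(series, CANONICAL_GRID, size)
        if expected is None:
            assert best is None
        else:
            assert best.frequencies == expected[0]
            assert best.mean_difference == pytest.approx(expected[1])


class TestGrading:
    @pytest.mark.parametrize(
        "pta,scale,expected",
        [
            (53.75, "WHO", (2, "moderate impairment")),
            (61, "WHO", (3, "severe impairment")),
            (80, "WHO", (3, "severe impairment")),
            (70, "WHO", (3, "severe impairment")),
            (70, "EU", (3, "severe impairment")),
            (94, "EU", (3, "severe impairment")),
            (69.9, "EU", (2, "moderate impairment")),
            (-10, "WHO", (0, "no impairment")),
            (120, "WHO", (4, "profound impairment")),
        ],
    )
    def test_band_lookup(self, scales, pta, scale, expected):
        assert grade(pta, scales[scale]) == expected

    @given(st.floats(min_value=-10, max_value=120, allow_nan=False),
           st.floats(min_value=0, max_value=130, allow_nan=False))
    @settings(max_examples=200)
    def test_grade_monotone_in_pta(self, scales, pta1, delta):
        pta2 = min(pta1 + delta, 120.0)
        for scale in scales.values():
            assert scale.grade(pta1)[0] <= scale.grade(pta2)[0]


def _record_from_difference(diffs, base_level=10.0, age=50, sex="female"):
    base = {f: base_level for f in CANONICAL_GRID}
    acute = {f: base_level + diffs.get(f, 0.0) for f in CANONICAL_GRID}
    return PatientRecord(
        acute=Audiogram(acute, ear="affected"),
        age=age,
        sex=sex,
        baseline_contralateral=Audiogram(base, role="baseline_contralateral"),
    )


class TestEvaluate:
    def test_worked_example_is_included(self, worked_example_record, default_criteria, scales, iso_table):
        report = evaluate(worked_example_record, default_criteria, scales, iso_table)
        assert report.severity_4pta == pytest.approx(53.75)
        assert report.severity_criterion_met
        assert report.grades["WHO"]["acute"] == (2, "moderate impairment")
        contra = next(
            c for c in report.comparisons if c.baseline_kind is BaselineKind.CONTRALATERAL
        )
        assert contra.max_window.window == (0.5, 2.0)
        assert contra.max_window.mean_difference == pytest.approx(140 / 3)
        assert {w.label for w in contra.qualifying_windows} == {
            "0.125-0.5 kHz", "0.25-1 kHz", "0.5-2 kHz", "1-3 kHz", "2-4 kHz",
        }
        assert report.recommendations[BaselineKind.CONTRALATERAL] is Recommendation.INCLUDE
        assert report.recommendations[BaselineKind.PREVIOUS] is Recommendation.NOT_COMPUTABLE

    def test_normative_baseline_synthesized_from_age_and_sex(self, worked_example_record):
        report = evaluate(worked_example_record)
        norm = next(c for c in report.comparisons if c.baseline_kind is BaselineKind.NORMATIVE)
        assert norm.computable
        # the normative median for a 65-year-old is nonzero, so the diff
        # series differs from the raw acute thresholds
        assert norm.max_window.mean_difference < pure_tone_average(worked_example_record.acute)

    def test_normative_better_than_contralateral_gives_larger_max_window(
        self, worked_example_record, iso_table
    ):
        # wherever every normative threshold is lower (better) than the
        # contralateral ear's, the normative comparison cannot yield a
        # smaller maximum window mean
        from audioscreen import normative_audiogram

        report = evaluate(worked_example_record)
        norm_ag = normative_audiogram(65, "female", CANONICAL_GRID, iso_table)
        contra_ag = worked_example_record.baseline_contralateral
        if all(norm_ag[f] <= contra_ag[f] for f in CANONICAL_GRID):
            by_kind = {c.baseline_kind: c for c in report.comparisons}
            assert (
                by_kind[BaselineKind.NORMATIVE].max_window.mean_difference
                >= by_kind[BaselineKind.CONTRALATERAL].max_window.mean_difference
            )

    def test_zero_criteria_disable_everything(self, worked_example_record):
        report = evaluate(worked_example_record, InclusionCriteria(0, 0))
        assert report.severity_criterion_met
        for kind, rec in report.recommendations.items():
            comp = next(c for c in report.comparisons if c.baseline_kind is kind)
            if comp.computable:
                assert rec is Recommendation.INCLUDE

    def test_severity_met_but_no_window_reaches_criterion(self):
        # every per-frequency difference stays below the criterion, so no
        # window mean can reach it (windows average their members)
        diffs = {f: 25.0 for f in CANONICAL_GRID}
        record = _record_from_difference(diffs, base_level=40.0, age=None, sex="unspecified")
        report = evaluate(record, InclusionCriteria(50.0, 30.0))
        assert report.severity_criterion_met
        for kind, rec in report.recommendations.items():
            comp = next(c for c in report.comparisons if c.baseline_kind is kind)
            if comp.computable:
                assert rec is Recommendation.EXCLUDE
                # brute-force confirmation over all windows
                for w in comp.windows:
                    if w.complete:
                        assert w.mean_difference < 30.0

    def test_severity_comparison_is_inclusive_at_the_boundary(self):
        record = _record_from_difference({f: 40.0 for f in CANONICAL_GRID}, base_level=10.0)
        # acute constant 50 -> 4PTA exactly 50, criterion 50 -> met
        report = evaluate(record, InclusionCriteria(50.0, 30.0))
        assert report.severity_4pta == pytest.approx(50.0)
        assert report.severity_criterion_met
        assert report.recommendations[BaselineKind.CONTRALATERAL] is Recommendation.INCLUDE

    def test_invalid_data_check_yields_not_computable(self, default_criteria):
        record = PatientRecord(acute=Audiogram({0.5: 50}))
        report = evaluate(record, default_criteria)
        assert not report.data_check.valid
        assert all(r is Recommendation.NOT_COMPUTABLE for r in report.recommendations.values())

    def test_unspecified_sex_makes_normative_not_computable(self, default_criteria):
        base = {f: 10.0 for f in CANONICAL_GRID}
        record = PatientRecord(
            acute=Audiogram({f: 60.0 for f in CANONICAL_GRID}),
            baseline_contralateral=Audiogram(base, role="baseline_contralateral"),
        )
        report = evaluate(record, default_criteria)
        assert report.recommendations[BaselineKind.NORMATIVE] is Recommendation.NOT_COMPUTABLE
        assert report.recommendations[BaselineKind.CONTRALATERAL] is Recommendation.INCLUDE

    @given(
        st.floats(min_value=0, max_value=80),
        st.floats(min_value=0, max_value=60),
        st.floats(min_value=0, max_value=40),
        st.floats(min_value=0, max_value=60),
    )
    @settings(max_examples=100)
    def test_raising_criteria_never_converts_exclude_to_include(self, sev, diff, d_sev, d_diff):
        rng = np.random.default_rng(12345)
        base = {f: v for f, v in zip(CANONICAL_GRID, rng.uniform(0, 40, 9))}
        acute = {f: min(v + d, 115) for (f, v), d in zip(base.items(), rng.uniform(0, 70, 9))}
        record = PatientRecord(
            acute=Audiogram(acute),
            baseline_contralateral=Audiogram(base, role="baseline_contralateral"),
        )
        lo = evaluate(record, InclusionCriteria(sev, diff))
        hi = evaluate(record, InclusionCriteria(min(sev + d_sev, 120), diff + d_diff))
        for kind in lo.recommendations:
            if lo.recommendations[kind] is Recommendation.EXCLUDE:
                assert hi.recommendations[kind] is not Recommendation.INCLUDE

    def test_lower_bound_property(self):
        # if every shared difference >= D, the max window mean is >= D
        rng = np.random.default_rng(7)
        D = 30.0
        base = {f: v for f, v in zip(CANONICAL_GRID, rng.uniform(0, 30, 9))}
        acute = {f: v + D + rng.uniform(0, 20) for f, v in base.items()}
        record = PatientRecord(
            acute=Audiogram(acute),
            baseline_contralateral=Audiogram(base, role="baseline_contralateral"),
        )
        report = evaluate(record, InclusionCriteria(0, D))
        contra = next(c for c in report.comparisons if c.baseline_kind is BaselineKind.CONTRALATERAL)
        assert contra.max_window.mean_difference >= D

    def test_decision_invariant_to_frequency_storage_order(self, default_criteria):
        diffs = dict(zip(CANONICAL_GRID, [5, 10, 35, 40, 35, 20, 10, 5, 0]))
        record = _record_from_difference(diffs, base_level=30.0)
        shuffled = PatientRecord(
            acute=Audiogram(dict(reversed(list(record.acute.thresholds.items())))),
            age=record.age,
            sex=record.sex,
            baseline_contralateral=Audiogram(
                dict(reversed(list(record.baseline_contralateral.thresholds.items()))),
                role="baseline_contralateral",
            ),
        )
        r1 = evaluate(record, default_criteria)
        r2 = evaluate(shuffled, default_criteria)
        assert r1.recommendations == r2.recommendations
        assert r1.severity_4pta == r2.severity_4pta


class TestRecruitmentRate:
    def test_all_included(self, worked_example_record):
        reports = [evaluate(worked_example_record, InclusionCriteria(0, 0))] * 10
        rr = recruitment_rate(reports)
        assert (rr.eligible_count, rr.total, rr.rate) == (10, 10, 1.0)

    def test_empty_cohort_rate_undefined(self):
        rr = recruitment_rate([])
        assert rr.total == 0 and rr.rate is None

    def test_policy_uses_first_computable_baseline(self, worked_example_record, default_criteria):
        report = evaluate(worked_example_record, default_criteria)
        # previous baseline missing -> contralateral decides
        assert is_eligible(report, [BaselineKind.PREVIOUS, BaselineKind.CONTRALATERAL])
        # a policy of only the missing baseline yields not eligible
        assert not is_eligible(report, [BaselineKind.PREVIOUS])
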