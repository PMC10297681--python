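"""Speech-effect parsing and cohort statistics on the packaged syndrome table."""
import pytest

from voicechain.phenotype import (
    SpeechCategory as C,
)
from voicechain.phenotype import (
    SyndromeRecord,
    build_cohort,
    category_stats,
    cooccurrence_stats,
    parse_effects,
)


class TestParseEffects:
    @pytest.mark.parametrize("text,expected", [
        ("Del, or Abs", {C.DELAYED, C.ABSENT}),
        ("Norm", {C.NORMAL}),
        ("Apr or Idio", {C.APRAXIC, C.IDIOSYNCRATIC}),
        ("Dysarthric, Abs; Imp", {C.DYSARTHRIC, C.ABSENT, C.IMPAIRED}),
        ("No significant anomaly reports", {C.NORMAL}),
        ("Sensorineural hearing loss", {C.NORMAL}),
        ("Norm to Abs", {C.NORMAL, C.ABSENT}),
        ("", set()),
        ("Not available", set()),
    ])
    def test_examples(self, text, expected):
        assert parse_effects(text) == expected

    def test_order_insensitive(self):
        assert parse_effects("Del or Imp") == parse_effects("Imp or Del")

    def test_tokens_are_word_bounded(self):
        # "Absolute" must not trigger the Abs code
        assert C.ABSENT not in parse_effects("Absolute pitch")


def _rec(name, vn2, conn, effects, vn1=0, c1=0):
    return SyndromeRecord.from_row(name, vn1, c1, vn2, conn, effects_text=effects)


class TestBuildCohort:
    def test_fixture_cohort_size(self, cohort):
        assert cohort.size == 73
        assert [r.name for r in cohort.excluded] == ["16q22"]

    def test_duplicate_regions_merged_with_union_of_categories(self, cohort):
        by_name = {r.name: r for r in cohort.records}
        merged = by_name["15q11-q13"]
        assert set(merged.merged_names) == {"15q11-q13", "15q11-q13"}
        assert {C.DELAYED, C.IMPAIRED, C.ABSENT} <= merged.categories
        assert merged.vn2_count == 30 and merged.vn2_connectivity == 230
        xq28 = by_name["Xq28"]
        assert {C.NORMAL, C.ABSENT, C.DELAYED} <= xq28.categories
        assert xq28.vn2_count == 64

    def test_clean_list_unchanged(self):
        records = [_rec("A", 5, 10, "Del"), _rec("B", 2, 3, "Norm")]
        cohort = build_cohort(records)
        assert cohort.size == 2 and cohort.excluded == ()

    def test_conflicting_duplicate_counts_error(self):
        records = [_rec("A", 5, 10, "Del"), _rec("A", 6, 10, "Imp")]
        with pytest.raises(ValueError, match="ambiguous merge"):
            build_cohort(records)


class TestCooccurrence:
    def test_fixture_chain_level_split(self, cohort):
        co = cooccurrence_stats(cohort)
        assert co.n_level1 == 17
        assert co.n_level2_only == 56

    def test_fixture_anomaly_rates(self, cohort):
        co = cooccurrence_stats(cohort)
        assert co.pct_level1_with_anomaly == 100.0
        assert co.pct_level2_with_anomaly == 91.8

    def test_single_normal_syndrome(self):
        cohort = build_cohort([_rec("A", 5, 10, "Norm")])
        co = cooccurrence_stats(cohort)
        assert co.n_level1 == 0
        assert co.pct_level2_with_anomaly == 0.0

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            cooccurrence_stats(build_cohort([_rec("A", 1, 1, "Not available")]))


class TestCategoryStats:
    def test_fixture_absent_row_matches_reference(self, cohort):
        rows, _ = category_stats(cohort)
        absent = next(s for s in rows if s.category is C.ABSENT)
        assert absent.count == 19
        assert round(absent.mean_count) == 60
        assert absent.median_count == 46
        assert round(absent.mean_connectivity) == 902
        assert absent.median_connectivity == 718

    def test_fixture_normal_group_is_exclusively_normal_rows(self, cohort):
        rows, _ = category_stats(cohort)
        normal = next(s for s in rows if s.category is C.NORMAL)
        assert normal.count == 6
        assert round(normal.mean_count) == 32
        assert round(normal.mean_connectivity) == 404
        inclusive_rows, _ = category_stats(cohort, normal_exclusive=False)
        normal_incl = next(s for s in inclusive_rows if s.category is C.NORMAL)
        assert normal_incl.count > 6  # mixed normal/anomaly rows join

    def test_idiosyncratic_folds_into_apraxic_by_default(self, cohort):
        rows, _ = category_stats(cohort)
        assert all(s.category is not C.IDIOSYNCRATIC for s in rows)
        unfolded, _ = category_stats(cohort, fold_idiosyncratic=False)
        idio = next(s for s in unfolded if s.category is C.IDIOSYNCRATIC)
        assert idio.count == 5

    def test_fixture_severity_extremes_and_tiebreak(self, cohort):
        """The robust part of the severity ordering: normal least, absent most,
        and the apraxic/dysarthric near-tie resolved by connectivity."""
        _, ordering = category_stats(cohort)
        assert ordering[0] is C.NORMAL
        assert ordering[-1] is C.ABSENT
        assert ordering.index(C.APRAXIC) < ordering.index(C.DYSARTHRIC)

    def test_single_syndrome_mean_equals_median(self):
        cohort = build_cohort([_rec("A", 7, 20, "Abs")])
        rows, _ = category_stats(cohort)
        absent = next(s for s in rows if s.category is C.ABSENT)
        assert absent.mean_count == absent.median_count == 7

    def test_hand_set_counts(self):
        cohort = build_cohort([
            _rec("A", 2, 1, "Dys"), _rec("B", 4, 2, "Dys"), _rec("C", 6, 3, "Dys"),
        ])
        rows, _ = category_stats(cohort)
        dys = next(s for s in rows if s.category is C.DYSARTHRIC)
        assert dys.mean_count == 4 and dys.median_count == 4

    def test_even_count_median_is_midpoint(self):
        cohort = build_cohort([_rec("A", 2, 1, "Del"), _rec("B", 5, 2, "Del")])
        rows, _ = category_stats(cohort)
        d = next(s for s in rows if s.category is C.DELAYED)
        assert d.median_count == 3.5

    def test_empty_category_reported_null(self):
        cohort = build_cohort([_rec("A", 2, 1, "Del")])
        rows, _ = category_stats(cohort)
        absent = next(s for s in rows if s.category is C.ABSENT)
        assert absent.count == 0 and absent.mean_count is None

    def test_multiplicity_at_least_cohort_size(self, cohort):
        rows, _ = category_stats(cohort)
        assert sum(s.count for s in rows) >= cohort.size
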