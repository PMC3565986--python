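"""He/Ho/PIC estimators, allele classes, concordance, transferability, attrition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssrkit.io import AmplificationTable, GenotypeTable
from ssrkit.stats import (
    AlleleFrequencies,
    AttritionModel,
    NoDataError,
    aggregate_stats,
    allele_frequencies,
    attrition_forward,
    attrition_required,
    classify_allele_frequencies,
    expected_heterozygosity,
    marker_summary,
    observed_heterozygosity,
    pic,
    round_half_up,
    size_concordance,
    transferability,
)


def freqs(*ps, marker="m", n=10):
    return AlleleFrequencies(marker=marker, freqs={100 + 2 * i: p for i, p in enumerate(ps)},
                             n_genotyped=n)


def table_from_calls(calls_per_ind, marker="m1"):
    individuals = [f"i{k}" for k in range(len(calls_per_ind))]
    calls = {(ind, marker): c for ind, c in zip(individuals, calls_per_ind)}
    return GenotypeTable(individuals, [marker], calls)


class TestAlleleFrequencies:
    def test_symmetric_heterozygotes(self):
        table = table_from_calls([(150.0, 152.0)] * 4)
        f = allele_frequencies(table, "m1")
        assert f.freqs == {150.0: 0.5, 152.0: 0.5}
        assert f.n_genotyped == 4

    def test_missing_excluded_from_denominator(self):
        table = table_from_calls([(150.0, 150.0), (150.0, 150.0), None, None])
        f = allele_frequencies(table, "m1")
        assert f.freqs == {150.0: 1.0} and f.n_genotyped == 2

    def test_copy_counting_by_hand(self):
        table = table_from_calls([(150.0, 150.0), (150.0, 152.0), (152.0, 154.0)])
        f = allele_frequencies(table, "m1")
        assert f.freqs[150.0] == pytest.approx(0.5)
        assert f.freqs[152.0] == pytest.approx(1 / 3)
        assert f.freqs[154.0] == pytest.approx(1 / 6)

    def test_all_missing_is_no_data(self):
        table = table_from_calls([None, None])
        with pytest.raises(NoDataError, match="no_data"):
            allele_frequencies(table, "m1")


class TestDiversityStatistics:
    @pytest.mark.parametrize(
        "ps,he", [((1.0,), 0.0), ((0.5, 0.5), 0.5), ((0.25,) * 4, 0.75)]
    )
    def test_expected_heterozygosity(self, ps, he):
        assert expected_heterozygosity(freqs(*ps)) == pytest.approx(he)

    @pytest.mark.parametrize(
        "ps,value", [((1.0,), 0.0), ((0.5, 0.5), 0.375), ((0.25,) * 4, 0.703125)]
    )
    def test_pic_botstein(self, ps, value):
        assert pic(freqs(*ps)) == pytest.approx(value)

    def test_observed_heterozygosity(self):
        assert observed_heterozygosity(table_from_calls([(150.0, 150.0)] * 3), "m1") == 0.0
        assert observed_heterozygosity(table_from_calls([(150.0, 152.0)] * 3), "m1") == 1.0
        calls = [(150.0, 152.0)] * 3 + [(150.0, 150.0)] * 7 + [None]
        assert observed_heterozygosity(table_from_calls(calls), "m1") == pytest.approx(0.3)

    @given(
        st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=1, max_size=8)
    )
    @settings(max_examples=200, derandomize=True)
    def test_pic_bounded_by_he(self, weights):
        total = sum(weights)
        f = freqs(*[w / total for w in weights])
        he, p = expected_heterozygosity(f), pic(f)
        assert 0 <= p <= he + 1e-12 < 1
        if len(weights) == 1:
            assert p == he == 0


class TestAlleleClasses:
    def test_one_per_class(self):
        out = classify_allele_frequencies([freqs(0.04, 0.2, 0.76)])
        assert out.counts == {"rare": 1, "intermediate": 1, "abundant": 1}
        assert sum(out.fractions.values()) == pytest.approx(1.0)

    def test_boundaries_are_intermediate(self):
        out = classify_allele_frequencies([freqs(0.05, 0.30, 0.65)])
        assert out.counts == {"rare": 0, "intermediate": 2, "abundant": 1}

    def test_pooled_fractions(self):
        db = [freqs(0.5, 0.5, marker=f"m{i}") for i in range(10)]
        out = classify_allele_frequencies(db)
        assert out.fractions["abundant"] == 1.0 and out.total == 20


class TestMarkerSummary:
    def test_monomorphic_marker(self):
        rows = marker_summary(table_from_calls([(99.0, 99.0)] * 4))
        (row,) = rows
        assert not row.polymorphic
        assert row.he == row.ho == row.pic == 0.0
        assert row.allele_count == 1 and row.size_range == (99.0, 99.0)

    def test_no_data_flagged_and_skipped_in_aggregates(self, small_genotypes):
        calls = dict(small_genotypes.calls)
        for ind in small_genotypes.individuals:
            calls[(ind, "m3")] = None
        table = GenotypeTable(small_genotypes.individuals, small_genotypes.markers, calls)
        rows = marker_summary(table)
        assert [r.no_data for r in rows] == [False, False, True]
        agg = aggregate_stats(rows)
        assert agg["n_markers"] == 2

    def test_aggregate_report(self, small_genotypes):
        rows = marker_summary(small_genotypes)
        agg = aggregate_stats(rows)
        assert agg["n_polymorphic"] == 2
        assert agg["total_alleles"] == 2 + 3 + 1
        assert agg["mean_alleles_per_polymorphic"] == pytest.approx(2.5)
        assert agg["min_pic"] <= agg["mean_pic"] <= agg["max_pic"]


class TestSizeConcordance:
    @pytest.mark.parametrize(
        "expected,lo,hi,contains,within",
        [
            (250, 240, 260, True, True),
            (250, 270, 280, False, False),  # 280 > 275 breaks the 10% band
            (250, 255, 270, False, True),
            (250, 225, 275, True, True),    # band endpoints inclusive
        ],
    )
    def test_flags(self, expected, lo, hi, contains, within):
        out = size_concordance(expected, (lo, hi), 0.10)
        assert (out.contains, out.within_tolerance) == (contains, within)


class TestTransferability:
    def _amp(self, hits, n, species="spA"):
        markers = [f"m{i}" for i in range(n)]
        amplified = {(m, species): i < hits for i, m in enumerate(markers)}
        return AmplificationTable(markers, [species], amplified)

    def test_published_survey_fraction(self):
        assert transferability(self._amp(184, 198))["spA"] == 92.9

    def test_all_true(self):
        assert transferability(self._amp(3, 3))["spA"] == 100.0

    def test_round_half_up(self):
        assert transferability(self._amp(2, 3))["spA"] == 66.7
        assert round_half_up(100 * 1 / 8, 1) == 12.5
        assert round_half_up(0.25, 1) == 0.3  # half rounds up, not to even

    def test_marker_order_invariance(self, rng):
        n = 37
        flags = rng.random(n) < 0.6
        markers = [f"m{i}" for i in range(n)]
        amp1 = AmplificationTable(
            markers, ["sp"], {(m, "sp"): bool(f) for m, f in zip(markers, flags)}
        )
        order = rng.permutation(n)
        amp2 = AmplificationTable(
            [markers[i] for i in order], ["sp"],
            {(markers[i], "sp"): bool(flags[i]) for i in order},
        )
        assert transferability(amp1) == transferability(amp2)


class TestAttrition:
    def test_forward_empty_and_basic(self):
        empty = AttritionModel((), ())
        assert attrition_forward(100, empty) == [100]
        model = AttritionModel(("a", "b"), (0.25, 0.5))
        assert attrition_forward(1000, model) == [1000, 750, 375]

    def test_forward_rounds_half_up(self):
        model = AttritionModel(("poly",), (0.5,))
        assert attrition_forward(729, model) == [729, 365]  # 364.5 -> 365

    def test_required_single_step(self):
        model = AttritionModel(("poly",), (0.5,))
        assert attrition_required(198, model) == [396, 198]
        assert attrition_required(0, model) == [0, 0]

    def test_required_46pct_step(self):
        model = AttritionModel(("identify",), (0.46,))
        assert attrition_required(396, model) == [733, 396]  # 396/0.54 = 733.3

    def test_rate_one_rejected(self):
        with pytest.raises(ValueError):
            AttritionModel(("x",), (1.0,))

    @given(st.integers(0, 10_000), st.lists(st.floats(0, 0.5), max_size=4))
    @settings(max_examples=200, derandomize=True)
    def test_forward_required_inverse_up_to_rounding(self, start, rates):
        model = AttritionModel(tuple(f"s{i}" for i in range(len(rates))), tuple(rates))
        forward = attrition_forward(start, model)
        back = attrition_required(forward[-1], model)
        assert len(back) == len(forward)
        assert back[-1] == forward[-1]
        for a, b in zip(forward, back):
            # half-unit rounding each way, amplified by survival <= 1/2 per
            # step when rates stay below 50%
            assert abs(a - b) <= 2 ** len(rates) + 1
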