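import numpy as np
import pandas as pd
import pytest

from rdscentral import (
    compute_baseline,
    flag_deviant,
    one_hot_encode,
    score_attributes,
)
from rdscentral.exceptionality import BaselineEntry
from rdscentral.selection import CentralNodeSet, SelectedNode

from conftest import respondent_table


def feature_matrix(columns, city="c"):
    n = len(next(iter(columns.values())))
    rows = [(f"r{i:03d}", city, "") for i in range(n)]
    return one_hot_encode(respondent_table(rows, extra_columns=columns))


def central_set(ids, city="c", measure="betweenness"):
    members = tuple(
        SelectedNode(node_id=i, component_id=ids[0], rank=r + 1, score=1.0)
        for r, i in enumerate(ids)
    )
    return CentralNodeSet(
        city=city, measure=measure, members=members, k_per_component=5, m_components=3
    )


class TestBaseline:
    def test_all_zero_binary(self):
        fm = feature_matrix({"b": [0.0] * 10})
        entry = compute_baseline(fm, "c")["b"]
        assert entry.mean == 0.0 and entry.sd == 0.0

    def test_two_value_population_and_sample_forms(self):
        fm = feature_matrix({"b": [0.0, 1.0]})
        pop = compute_baseline(fm, "c", sd_form="population")["b"]
        samp = compute_baseline(fm, "c", sd_form="sample")["b"]
        assert pop.mean == 0.5 and pop.sd == pytest.approx(0.5)
        assert samp.sd == pytest.approx(np.sqrt(0.5))

    def test_city_restriction_and_unavailable_attribute(self):
        rows = [("a", "c1", ""), ("b", "c1", ""), ("d", "c2", ""), ("e", "c2", "")]
        table = respondent_table(rows, {"x": [1.0, 0.0, np.nan, np.nan]})
        fm = one_hot_encode(table)
        b1 = compute_baseline(fm, "c1")
        b2 = compute_baseline(fm, "c2")
        assert b1["x"].mean == 0.5 and b1["x"].n_observed == 2
        assert not b2.available("x")


class TestFlagDeviant:
    def test_binary_low_prevalence_yes_is_deviant(self):
        p = 0.05
        entry = BaselineEntry(p, np.sqrt(p * (1 - p)), 100)
        assert flag_deviant(1.0, entry)

    def test_binary_half_prevalence_yes_is_not_deviant(self):
        entry = BaselineEntry(0.5, 0.5, 100)
        assert not flag_deviant(1.0, entry)

    def test_value_at_mean_never_deviant(self):
        assert not flag_deviant(0.3, BaselineEntry(0.3, 0.0, 10))
        assert not flag_deviant(0.3, BaselineEntry(0.3, 0.2, 10))

    def test_zero_sd_flags_any_difference(self):
        assert flag_deviant(1.0, BaselineEntry(0.0, 0.0, 10))

    def test_binary_boundaries_p02_and_p08(self):
        # |1-p| > 2 sqrt(p(1-p)) iff p < 0.2; |0-p| > 2 sqrt(p(1-p)) iff p > 0.8
        # grid avoids landing exactly on 0.2/0.8, where float rounding of
        # sqrt(p(1-p)) would arbitrarily decide the strict inequality
        for p in np.linspace(0.0101, 0.9899, 197):
            entry = BaselineEntry(p, np.sqrt(p * (1 - p)), 1000)
            assert flag_deviant(1.0, entry) == (p < 0.2)
            assert flag_deviant(0.0, entry) == (p > 0.8)


class TestScoreAttributes:
    def build(self, deviant_count, n_central=15, n_background=185):
        """Binary marker: `deviant_count` of the central nodes carry it, plus
        a 5% background, keeping city prevalence far below the 0.2 boundary."""
        n = n_central + n_background
        values = np.zeros(n)
        values[:deviant_count] = 1.0  # central carriers
        values[n_central : n_central + 9] = 1.0  # background carriers (~5%)
        fm = feature_matrix({"marker": values})
        central = central_set([f"r{i:03d}" for i in range(n_central)])
        baseline = compute_baseline(fm, "c")
        return central, fm, baseline

    @pytest.mark.parametrize(
        "count,score", [(4, 0.2667), (5, 0.3333), (6, 0.4000), (7, 0.4667)]
    )
    def test_published_score_arithmetic(self, count, score):
        central, fm, baseline = self.build(count)
        records = score_attributes(central, fm, baseline)
        by_attr = {r.attribute: r for r in records}
        assert by_attr["marker"].deviant_count == count
        assert by_attr["marker"].score_4dp == score

    def test_below_threshold_absent(self):
        central, fm, baseline = self.build(3)
        assert score_attributes(central, fm, baseline, min_count=4) == []

    def test_missing_values_count_as_non_deviant(self):
        central, fm, baseline = self.build(4)
        fm.values.loc["r000", "marker"] = np.nan  # one deviant becomes missing
        records = score_attributes(central, fm, baseline)
        assert records == []  # 3 observed deviants < 4

    def test_sorted_by_descending_score_then_name(self):
        n = 200
        cols = {
            "aa": np.r_[np.ones(5), np.zeros(n - 5)],
            "bb": np.r_[np.ones(7), np.zeros(n - 7)],
            "cc": np.r_[np.ones(5), np.zeros(n - 5)],
        }
        fm = feature_matrix(cols)
        central = central_set([f"r{i:03d}" for i in range(15)])
        records = score_attributes(central, fm, compute_baseline(fm, "c"))
        assert [r.attribute for r in records] == ["bb", "aa", "cc"]

    def test_score_is_count_over_realized_set_size(self):
        central, fm, baseline = self.build(6, n_central=13)
        rec = score_attributes(central, fm, baseline)[0]
        assert rec.set_size == 13
        assert rec.score == pytest.approx(6 / 13)
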