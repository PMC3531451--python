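"""ppm normalization, matching, two-fold classification, overlap."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mdgel.differential import (
    NormalizationError,
    class_proportions,
    classify_twofold,
    match_spots,
    normalize_ppm,
    overlap_analysis,
    passing,
)
from mdgel.fixtures import load_catalog, load_table2, load_table3
from mdgel.model import ProteinEntry, SpotRecord, SpotTable


def table_from_iods(iods, gel_id="G"):
    return SpotTable(gel_id, [
        SpotRecord(str(i), gel_id, iod_raw=v) for i, v in enumerate(iods)
    ])


def pair_of_ppm(case_ppm, control_ppm, spot_id="x"):
    return (
        SpotRecord(spot_id, "case", ppm=case_ppm),
        SpotRecord(spot_id, "control", ppm=control_ppm),
    )


class TestNormalizePpm:
    def test_single_spot_gets_full_million(self):
        out = normalize_ppm(table_from_iods([123.4]))
        assert out.records[0].ppm == pytest.approx(1_000_000.0)

    def test_proportionality(self):
        out = normalize_ppm(table_from_iods([100.0, 300.0, 600.0]))
        assert [r.ppm for r in out] == pytest.approx([100000, 300000, 600000])

    def test_closure(self):
        out = normalize_ppm(table_from_iods([3.0, 7.0, 11.0, 0.5]))
        assert out.ppm_closure_ok()

    def test_all_zero_gel_rejected(self):
        with pytest.raises(NormalizationError):
            normalize_ppm(table_from_iods([0.0, 0.0]))

    @given(st.lists(st.floats(min_value=0.01, max_value=1e6), min_size=1, max_size=30),
           st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, iods, c):
        base = normalize_ppm(table_from_iods(iods))
        scaled = normalize_ppm(table_from_iods([v * c for v in iods]))
        for a, b in zip(base, scaled):
            assert b.ppm == pytest.approx(a.ppm, rel=1e-9)


class TestMatchSpots:
    def test_fixture_mode_pairs_all_published_rows(self):
        t2 = load_table2()
        pairs = match_spots(t2["TM"], t2["CON"])
        assert len(pairs) == 48
        assert all(a is not None and b is not None for a, b in pairs)

    def test_identical_coordinates_pair_perfectly(self):
        def table(gel):
            return SpotTable(gel, [
                SpotRecord(f"{gel}{i}", gel, pi_coord=4.0 + i, mw_coord=20.0 + 5 * i,
                           ppm=100.0)
                for i in range(5)
            ])
        pairs = match_spots(table("a"), table("b"))
        assert len(pairs) == 5
        assert all(a is not None and b is not None for a, b in pairs)

    def test_displacement_beyond_tolerance_unmatches(self):
        a = SpotTable("a", [SpotRecord("a1", "a", pi_coord=5.0, mw_coord=30.0, ppm=1.0)])
        b = SpotTable("b", [SpotRecord("b1", "b", pi_coord=5.5, mw_coord=30.0, ppm=1.0)])
        pairs = match_spots(a, b, tol=(0.1, 0.05))
        assert (pairs[0][1] is None) and (pairs[1][0] is None)
        assert len(pairs) == 2

    def test_empty_tables(self):
        assert match_spots(SpotTable("a"), SpotTable("b")) == []


class TestClassifyTwofold:
    @pytest.mark.parametrize("case,control,direction,passes", [
        (1526.9, 345.8, "up", True),     # apolipoprotein AI spot
        (480.4, 1075.2, "down", True),   # myoglobin spot
        (150.0, 100.0, "up", False),     # ratio 1.5, sub-threshold
        (200.0, 100.0, "up", True),      # boundary: exactly two-fold passes
        (100.0, 200.0, "down", True),    # boundary: exactly half passes
        (100.0, 100.0, "unchanged", False),
    ])
    def test_worked_examples(self, case, control, direction, passes):
        [rec] = classify_twofold([pair_of_ppm(case, control)])
        assert rec.direction == direction
        assert rec.passes_twofold is passes

    def test_zero_control_presence_call(self):
        [rec] = classify_twofold([pair_of_ppm(50.0, 0.0)])
        assert math.isinf(rec.ratio) and rec.direction == "up"
        assert rec.passes_twofold and rec.presence_absence

    def test_zero_case_absence_call(self):
        [rec] = classify_twofold([pair_of_ppm(0.0, 50.0)])
        assert rec.ratio == 0.0 and rec.direction == "down"
        assert rec.passes_twofold and rec.presence_absence

    def test_absent_both_excluded(self):
        [rec] = classify_twofold([pair_of_ppm(0.0, 0.0)])
        assert rec.absent_both and not rec.passes_twofold

    def test_ordering_preserved(self):
        pairs = [pair_of_ppm(1.0, 2.0, spot_id=f"s{i}") for i in range(5)]
        recs = classify_twofold(pairs)
        assert [r.spot_id for r in recs] == [f"s{i}" for i in range(5)]

    @given(st.floats(min_value=0.01, max_value=1e5),
           st.floats(min_value=0.01, max_value=1e5))
    def test_case_control_swap_symmetry(self, a, b):
        [fwd] = classify_twofold([pair_of_ppm(a, b)])
        [rev] = classify_twofold([pair_of_ppm(b, a)])
        assert fwd.passes_twofold == rev.passes_twofold
        flip = {"up": "down", "down": "up", "unchanged": "unchanged"}
        assert rev.direction == flip[fwd.direction]

    def test_bad_fold_threshold(self):
        with pytest.raises(ValueError):
            classify_twofold([], fold=1.0)


class TestOverlap:
    def _published_records(self):
        t2, t3 = load_table2(), load_table3()
        recs_tm = classify_twofold(match_spots(t2["TM"], t2["CON"]))
        recs_cwp = classify_twofold(match_spots(t3["CWP"], t3["CON"]))
        return passing(recs_tm), passing(recs_cwp)

    def test_published_overlap_counts_and_identities(self):
        tm, cwp = self._published_records()
        summary = overlap_analysis(tm, cwp)
        assert summary.n_shared == 17
        assert summary.n_same_direction == 12
        assert summary.n_opposite_direction == 5
        assert summary.opposite_direction_ids == ["1704", "1705", "1706", "2503", "8701"]

    def test_disjoint_sets(self):
        a = classify_twofold([pair_of_ppm(10, 1, "a1")])
        b = classify_twofold([pair_of_ppm(10, 1, "b1")])
        s = overlap_analysis(a, b)
        assert (s.n_shared, s.n_same_direction, s.n_opposite_direction) == (0, 0, 0)

    def test_self_overlap_reflexive(self):
        tm, _ = self._published_records()
        s = overlap_analysis(tm, tm)
        assert s.n_shared == len(tm)
        assert s.n_opposite_direction == 0


class TestClassProportions:
    def test_catalog_inflammatory_fraction(self):
        frame = class_proportions(load_catalog()).set_index("functional_class")
        assert frame.loc["inflammatory", "count"] == 10
        assert frame.loc["inflammatory", "percent"] == pytest.approx(10.3)
        assert frame.loc["inflammatory", "percent_display"] == 10

    def test_single_class_is_100(self):
        frame = class_proportions([ProteinEntry("X", functional_class="metabolic")])
        assert frame["percent"].tolist() == [100.0]

    def test_percentages_sum_to_100(self):
        frame = class_proportions(load_catalog())
        assert frame["percent"].sum() == pytest.approx(100.0, abs=0.5)
        assert frame["count"].sum() == 97

    def test_empty_input_empty_result(self):
        assert len(class_proportions([])) == 0
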