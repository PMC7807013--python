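"""Bird-year strategy classification rules."""

import itertools
from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from partmig.strategy import (MIGRANT, RESIDENT, UNKNOWN, Evidence,
                              StrategyRules, classify_by_geolocator,
                              classify_by_isotope, classify_by_resighting,
                              classify_cohort, migrant_counts, reconcile,
                              sensitivity_analysis, strategy_consistency,
                              winter_year)

RULES = StrategyRules()


def _resight(rows):
    return pd.DataFrame(rows, columns=["bird_id", "date", "area"])


def _fixes(rows):
    return pd.DataFrame(rows, columns=["bird_id", "datetime", "latitude", "longitude"])


def _iso(rows):
    return pd.DataFrame(rows, columns=["bird_id", "collection_year", "d13c"])


class TestResighting:
    def test_in_window_gives_resident_for_following_season(self):
        out = classify_by_resighting(_resight([("b1", "2015-12-10", "A-rich")]), RULES)
        assert [e.verdict for e in out[("b1", 2016)]] == [RESIDENT]

    def test_outside_window_gives_nothing(self):
        out = classify_by_resighting(_resight([("b1", "2015-10-20", "A-rich")]), RULES)
        assert out == {}

    def test_window_boundaries_inclusive(self):
        out = classify_by_resighting(
            _resight([("b1", "2015-11-01", "A-rich"), ("b2", "2016-01-15", "A-rich")]),
            RULES)
        assert ("b1", 2016) in out and ("b2", 2016) in out

    def test_wintering_ground_sighting_is_migrant_evidence(self):
        out = classify_by_resighting(_resight([("b1", "2016-12-20", "Senegal")]), RULES)
        assert [e.verdict for e in out[("b1", 2017)]] == [MIGRANT]

    def test_in_area_records_never_emit_migrant(self):
        rows = [("b", f"2015-{m:02d}-10", "B-poor") for m in (11, 12)]
        out = classify_by_resighting(_resight(rows), RULES)
        assert all(e.verdict == RESIDENT for evs in out.values() for e in evs)

    def test_undated_record_rejected_with_row_reference(self):
        with pytest.raises(ValueError, match="rows"):
            classify_by_resighting(_resight([("b1", "not-a-date", "A-rich")]), RULES)


class TestGeolocator:
    def _win(self, bird, lats, year=2016):
        days = ["%d-11-%02d" % (year - 1, 5 + i) for i in range(len(lats))]
        return _fixes([(bird, f"{d}T12:00:00", la, -5.0) for d, la in zip(days, lats)])

    def test_all_north_of_floor_is_resident(self):
        out = classify_by_geolocator(self._win("b1", [37.1, 36.8, 37.0]), RULES)
        assert out[("b1", 2016)][0].verdict == RESIDENT

    def test_two_fixes_south_of_ceiling_is_migrant(self):
        out = classify_by_geolocator(self._win("b1", [37.0, 14.2, 14.9]), RULES)
        assert out[("b1", 2016)][0].verdict == MIGRANT

    def test_single_southern_fix_insufficient(self):
        out = classify_by_geolocator(self._win("b1", [37.0, 14.2]), RULES)
        assert out[("b1", 2016)][0].verdict == UNKNOWN

    def test_intermediate_band_is_unknown(self):
        out = classify_by_geolocator(self._win("b1", [37.0, 30.0]), RULES)
        ev = out[("b1", 2016)][0]
        assert ev.verdict == UNKNOWN and "intermediate" in ev.detail

    def test_no_winter_coverage_is_unknown_not_resident(self):
        fx = _fixes([("b1", "2016-03-10T12:00:00", 37.0, -5.0)])
        out = classify_by_geolocator(fx, RULES)
        ev = out[("b1", 2016)][0]
        assert ev.verdict == UNKNOWN and "no winter coverage" in ev.detail

    def test_latitude_bounds_enforced(self):
        with pytest.raises(ValueError, match="latitude"):
            classify_by_geolocator(self._win("b1", [95.0]), RULES)


class TestIsotope:
    @pytest.mark.parametrize("d13c,cutoff,verdict", [
        (-18.0, -20.0, MIGRANT),
        (-20.0, -20.0, UNKNOWN),   # strict inequality at the boundary
        (-19.8, -19.5, UNKNOWN),   # sensitivity-shifted cutoff
        (-19.8, -20.5, MIGRANT),
        (-23.5, -20.0, UNKNOWN),   # low value is indeterminate, never resident
    ])
    def test_cutoff_rule(self, d13c, cutoff, verdict):
        out = classify_by_isotope(_iso([("b1", 2016, d13c)]), cutoff)
        assert out[("b1", 2016)][0].verdict == verdict

    def test_never_emits_resident(self):
        rng = np.random.default_rng(0)
        samples = _iso([(f"b{i}", 2016, v)
                        for i, v in enumerate(rng.uniform(-30, -10, 200))])
        out = classify_by_isotope(samples, -20.0)
        assert all(e.verdict in (MIGRANT, UNKNOWN)
                   for evs in out.values() for e in evs)

    def test_missing_value_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            classify_by_isotope(_iso([("b1", 2016, np.nan)]), -20.0)

    @given(st.lists(st.floats(-35, -5), min_size=1, max_size=30),
           st.floats(-22, -18), st.floats(0.01, 2.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_migrant_set_shrinks_as_cutoff_rises(self, vals, c1, step):
        samples = _iso([(f"b{i}", 2016, v) for i, v in enumerate(vals)])
        mig = lambda cut: {k for k, evs in classify_by_isotope(samples, cut).items()
                           if evs[0].verdict == MIGRANT}
        assert mig(c1 + step) <= mig(c1)


class TestReconcile:
    def test_single_stream(self):
        call = reconcile("b", 2016, [Evidence("resighting", RESIDENT)])
        assert call.strategy == RESIDENT and not call.conflict

    def test_agreement(self):
        call = reconcile("b", 2016, [Evidence("isotope", MIGRANT),
                                     Evidence("geolocator", MIGRANT)])
        assert call.strategy == MIGRANT and not call.conflict

    def test_conflict_flagged_unknown(self):
        evs = [Evidence("resighting", RESIDENT), Evidence("isotope", MIGRANT)]
        call = reconcile("b", 2016, evs)
        assert call.strategy == UNKNOWN and call.conflict and len(call.evidence) == 2

    def test_no_determinate_evidence(self):
        call = reconcile("b", 2016, [Evidence("isotope", UNKNOWN)])
        assert call.strategy == UNKNOWN and not call.conflict

    def test_matches_exhaustive_truth_table(self):
        """On all 3-stream verdict combinations the reconciler equals the
        brute-force rule: agree -> that; none -> unknown; clash -> conflict."""
        verdicts = [MIGRANT, RESIDENT, UNKNOWN]
        for combo in itertools.product(verdicts, repeat=3):
            evs = [Evidence(s, v) for s, v in
                   zip(("resighting", "geolocator", "isotope"), combo)]
            call = reconcile("b", 2016, evs)
            det = {v for v in combo if v != UNKNOWN}
            if not det:
                assert call.strategy == UNKNOWN and not call.conflict
            elif len(det) == 1:
                assert call.strategy == det.pop() and not call.conflict
            else:
                assert call.strategy == UNKNOWN and call.conflict


class TestConsistency:
    def _calls(self, seqs):
        out = []
        for bird, seq in seqs.items():
            for year, s in seq.items():
                out.append(reconcile(bird, year, [Evidence("x", s)]))
        return out

    def test_consistent_and_switch_directions(self):
        summary = strategy_consistency(self._calls({
            "b1": {2015: MIGRANT, 2016: MIGRANT},
            "b2": {2015: MIGRANT, 2016: RESIDENT},
            "b3": {2015: RESIDENT, 2016: MIGRANT},
            "b4": {2015: RESIDENT},  # single year: excluded
        }))
        assert summary == {"individuals_multi_year": 3, "consistent": 1,
                           "migrant_to_resident": 1, "resident_to_migrant": 1}


class TestSensitivity:
    def test_example_cutoffs(self):
        samples = _iso([("b1", 2016, -19.8)])
        out = sensitivity_analysis(_resight([]), _fixes([]), samples)
        by = {c: calls[0].strategy for c, calls in out.items()}
        assert by[-20.5] == MIGRANT and by[-20.0] == MIGRANT and by[-19.5] == UNKNOWN

    def test_migrant_count_nonincreasing_in_cutoff(self, default_cohort):
        tables, _ = default_cohort
        out = sensitivity_analysis(tables["resightings"], tables["geolocator_fixes"],
                                   tables["feather_isotopes"])
        counts = migrant_counts(out)
        cs = sorted(counts)
        assert counts[cs[0]] >= counts[cs[1]] >= counts[cs[2]]


def test_winter_year_mapping():
    assert winter_year(date(2015, 12, 10), RULES) == 2016
    assert winter_year(date(2016, 1, 10), RULES) == 2016
    assert winter_year(date(2016, 6, 10), RULES) is None


def test_rules_validation():
    with pytest.raises(ValueError):
        StrategyRules(resident_lat_floor=20.0)  # ceiling above floor
    with pytest.raises(ValueError):
        StrategyRules(min_southern_fixes=0)
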