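"""Tape lookup rules, calibration validation and estimator invariants."""

import numpy as np
import pytest

from tapeweight.estimators import (
    BroselowCalibration,
    CalibrationError,
    LengthSegment,
    PawperCalibration,
    PawperSegmentRow,
    broselow_estimate,
    estimate_many,
    load_calibration,
    locate_segment,
    pawper_xl_mac_estimate,
    ralston_estimate,
    save_calibration,
)


@pytest.fixture
def small_pawper():
    """Hand-sized tape with the worked segment [80, 82.5)."""
    rows = (
        PawperSegmentRow(LengthSegment(77.5, 80.0), (12.5, 13.5, 14.5), (8.0, 9.5, 11.0, 12.5)),
        PawperSegmentRow(LengthSegment(80.0, 82.5), (13.0, 14.0, 15.0), (8.5, 10.0, 11.5, 13.0)),
        PawperSegmentRow(LengthSegment(82.5, 85.0), (13.2, 14.2, 15.2), (9.0, 10.5, 12.0, 13.5)),
    )
    return PawperCalibration(rows)


class TestLocateSegment:
    def test_lower_bound_belongs_to_segment(self, small_pawper):
        assert locate_segment(small_pawper.segments, 80.0) == 1

    def test_upper_bound_belongs_to_next(self, small_pawper):
        assert locate_segment(small_pawper.segments, 82.5) == 2

    def test_below_range_is_none(self, small_pawper):
        assert locate_segment(small_pawper.segments, 70.0) is None
        assert locate_segment(small_pawper.segments, 90.0) is None

    def test_nonpositive_length_rejected(self, small_pawper):
        with pytest.raises(ValueError):
            locate_segment(small_pawper.segments, 0.0)

    def test_vectorised_matches_linear_scan(self, calibrations):
        cal = calibrations["pawper_xl_mac"]
        rng = np.random.default_rng(42)
        lengths = rng.uniform(40.0, 140.0, size=1000)
        from tapeweight.estimators import _locate_many
        vec = _locate_many(cal.segments, lengths)
        for length, got in zip(lengths, vec):
            expect = locate_segment(cal.segments, length)
            assert (got == -1 and expect is None) or got == expect


class TestPawper:
    def test_worked_lookup(self, small_pawper):
        # length 81 -> segment [80, 82.5); mac 14.5 passes cut-offs 13.0 and 14.0
        res = pawper_xl_mac_estimate(small_pawper, 81.0, 14.5)
        assert res.in_range and res.segment_index == 1 and res.habitus_index == 2
        assert res.weight == pytest.approx(11.5)

    def test_mac_below_first_cutoff_gives_lowest_habitus(self, small_pawper):
        res = pawper_xl_mac_estimate(small_pawper, 81.0, 12.0)
        assert res.habitus_index == 0 and res.weight == pytest.approx(8.5)

    def test_mac_equal_to_cutoff_moves_up(self, small_pawper):
        res = pawper_xl_mac_estimate(small_pawper, 81.0, 14.0)
        assert res.habitus_index == 2

    def test_out_of_range_flagged_not_raised(self, small_pawper):
        res = pawper_xl_mac_estimate(small_pawper, 60.0, 14.0)
        assert not res.in_range and res.weight is None

    def test_mm_and_cm_mac_agree(self, small_pawper):
        a = pawper_xl_mac_estimate(small_pawper, 81.0, 14.5)
        b = pawper_xl_mac_estimate(small_pawper, 81.0, 145.0, mac_unit="mm")
        assert a == b

    def test_monotone_in_mac_random_probes(self, calibrations):
        cal = calibrations["pawper_xl_mac"]
        rng = np.random.default_rng(1)
        for _ in range(200):
            length = rng.uniform(50.0, 129.9)
            macs = np.sort(rng.uniform(10.0, 20.0, size=5))
            weights = [pawper_xl_mac_estimate(cal, length, m).weight for m in macs]
            assert all(b >= a for a, b in zip(weights, weights[1:]))

    def test_monotone_in_length_at_fixed_habitus(self, calibrations):
        cal = calibrations["pawper_xl_mac"]
        for h in range(7):
            col = [row.weights[h] for row in cal.rows]
            assert all(b >= a for a, b in zip(col, col[1:]))


class TestBroselow:
    def test_weight_read_from_segment(self, calibrations):
        cal = calibrations["broselow_2007B"]
        res = broselow_estimate(cal, 77.0)
        idx = locate_segment(cal.segments, 77.0)
        assert res.weight == cal.rows[idx][1]
        assert res.habitus_index is None

    def test_editions_are_isolated(self, calibrations):
        a = broselow_estimate(calibrations["broselow_2007B"], 90.0)
        b = broselow_estimate(calibrations["broselow_2011A"], 90.0)
        assert a.method == "broselow_2007B" and b.method == "broselow_2011A"
        assert a.weight != b.weight  # fixture editions differ by design

    def test_sweep_is_nondecreasing_step_function(self, calibrations):
        cal = calibrations["broselow_2007B"]
        lengths = np.arange(50.0, 130.0, 0.25)
        weights = [broselow_estimate(cal, x).weight for x in lengths]
        assert all(b >= a for a, b in zip(weights, weights[1:]))


class TestRalston:
    @pytest.mark.parametrize("mac_mm,band", [
        (114.9, 0),   # severe strictly below 115
        (115.0, 1),   # inclusive lower edge of moderate
        (125.0, 1),   # inclusive upper edge of moderate
        (125.1, 2),   # normal strictly above 125
    ])
    def test_band_boundaries(self, calibrations, mac_mm, band):
        res = ralston_estimate(calibrations["ralston"], 90.0, mac_mm)
        assert res.habitus_index == band

    def test_weight_nondecreasing_across_band_sweep(self, calibrations):
        cal = calibrations["ralston"]
        weights = [ralston_estimate(cal, 90.0, m).weight for m in np.arange(100.0, 140.0, 0.5)]
        assert all(b >= a for a, b in zip(weights, weights[1:]))

    def test_out_of_range(self, calibrations):
        assert not ralston_estimate(calibrations["ralston"], 30.0, 120.0).in_range


class TestTotalityAndVectorisation:
    def test_every_in_range_pair_maps_to_one_weight(self, calibrations):
        rng = np.random.default_rng(7)
        lengths = rng.uniform(50.0, 129.9, size=10_000)
        macs = rng.uniform(9.0, 20.0, size=10_000)
        for cal in calibrations.values():
            weights, ok, seg, _ = estimate_many(cal, lengths, mac_cm=macs)
            assert ok.all()
            assert np.isfinite(weights).all() and (weights > 0).all()

    def test_vectorised_equals_scalar_calls(self, calibrations):
        rng = np.random.default_rng(9)
        lengths = rng.uniform(45.0, 135.0, size=300)  # includes out-of-range
        macs = rng.uniform(9.0, 20.0, size=300)
        for name, cal in calibrations.items():
            weights, ok, _, _ = estimate_many(cal, lengths, mac_cm=macs)
            for i in range(len(lengths)):
                if name == "pawper_xl_mac":
                    res = pawper_xl_mac_estimate(cal, lengths[i], macs[i])
                elif name.startswith("broselow"):
                    res = broselow_estimate(cal, lengths[i])
                else:
                    res = ralston_estimate(cal, lengths[i], macs[i] * 10.0)
                assert ok[i] == res.in_range
                if res.in_range:
                    assert weights[i] == pytest.approx(res.weight)
                else:
                    assert np.isnan(weights[i])


class TestCalibrationValidation:
    def test_fixture_has_seven_habitus_weights(self, calibrations):
        assert all(len(r.weights) == 7 for r in calibrations["pawper_xl_mac"].rows)

    def test_overlapping_segments_rejected(self):
        with pytest.raises(CalibrationError, match="overlap"):
            BroselowCalibration("2007B", (
                (LengthSegment(75.0, 80.0), 10.0),
                (LengthSegment(79.0, 85.0), 11.0),
            ))

    def test_gap_rejected(self):
        with pytest.raises(CalibrationError, match="gap"):
            BroselowCalibration("2007B", (
                (LengthSegment(75.0, 80.0), 10.0),
                (LengthSegment(81.0, 85.0), 11.0),
            ))

    def test_nonincreasing_cutoffs_rejected(self):
        with pytest.raises(CalibrationError, match="cut-offs not increasing"):
            PawperSegmentRow(LengthSegment(80.0, 82.5), (14.0, 13.0), (8.0, 9.0, 10.0))

    def test_wrong_habitus_arity_rejected(self):
        with pytest.raises(CalibrationError, match="cut-offs"):
            PawperSegmentRow(LengthSegment(80.0, 82.5), (13.0,), (8.0, 9.0, 10.0))

    def test_decreasing_broselow_weight_names_row(self):
        with pytest.raises(CalibrationError, match="row 1"):
            BroselowCalibration("2007B", (
                (LengthSegment(75.0, 80.0), 10.0),
                (LengthSegment(80.0, 85.0), 9.0),
            ))

    def test_json_round_trip(self, tmp_path, calibrations):
        for name, cal in calibrations.items():
            path = tmp_path / f"{name}.json"
            save_calibration(cal, path)
            back = load_calibration(path)
            assert back == cal

    def test_broken_file_error_names_row(self, tmp_path, calibrations):
        import json
        from tapeweight.estimators import _calibration_to_dict
        doc = _calibration_to_dict(calibrations["broselow_2007B"])
        doc["rows"][2]["segment_lower_cm"] = doc["rows"][1]["segment_lower_cm"]  # overlap
        path = tmp_path / "broken.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(CalibrationError, match="row 2"):
            load_calibration(path)
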