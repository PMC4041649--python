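"""Body length, velocities, summaries, and trajectory comparison."""

import math

import numpy as np
import pytest

from mimizutrack.imaging_io import Calibration
from mimizutrack.kinematics import (
    CHAIN_LENGTH_CORRECTION,
    REFERENCE_BODY_LENGTH_MM,
    body_length,
    compare_trajectories,
    length_series,
    stretch_range,
    summarize,
    velocities,
)

from conftest import make_record, make_skeleton


class TestBodyLength:
    def test_axial_line_raw_metric(self, cal):
        skel = make_skeleton([(5, c) for c in range(101)], shape=(10, 110))
        raw = body_length(skel, (5, 0), (5, 100), cal, corrected=False)
        assert raw == pytest.approx(100 * 0.2)

    def test_diagonal_line_raw_metric(self, cal):
        skel = make_skeleton([(i, i) for i in range(11)], shape=(20, 20))
        raw = body_length(skel, (0, 0), (10, 10), cal, corrected=False)
        assert raw == pytest.approx(10 * math.sqrt(2) * 0.2)

    def test_calibrated_length_scales_raw_by_correction(self, cal):
        skel = make_skeleton([(5, c) for c in range(101)], shape=(10, 110))
        raw = body_length(skel, (5, 0), (5, 100), cal, corrected=False)
        assert body_length(skel, (5, 0), (5, 100), cal) == pytest.approx(
            raw * CHAIN_LENGTH_CORRECTION)

    def test_invariant_under_translation_and_rotation(self, cal):
        pixels = [(2, c) for c in range(2, 9)] + [(r, 8) for r in range(3, 7)]
        skel = make_skeleton(pixels, shape=(20, 20))
        base = body_length(skel, (2, 2), (6, 8), cal)
        moved = make_skeleton([(r + 5, c + 3) for r, c in pixels], shape=(20, 20))
        assert body_length(moved, (7, 5), (11, 11), cal) == pytest.approx(base)
        rotated = make_skeleton([(c, 19 - r) for r, c in pixels], shape=(20, 20))
        assert body_length(rotated, (2, 17), (8, 13), cal) == pytest.approx(base)

    def test_doubling_calibration_doubles_length(self, cal):
        skel = make_skeleton([(5, c) for c in range(30)], shape=(10, 40))
        one = body_length(skel, (5, 0), (5, 29), cal)
        two = body_length(skel, (5, 0), (5, 29),
                          Calibration(mm_per_pixel=0.4))
        assert two == pytest.approx(2 * one)

    def test_unreachable_head_errors(self, cal):
        skel = make_skeleton([(5, 0), (5, 1), (5, 10)], shape=(10, 20))
        with pytest.raises(ValueError, match="unreachable"):
            body_length(skel, (5, 0), (5, 10), cal)


class TestVelocities:
    def test_three_four_five_displacement(self, cal):
        recs = [make_record(0, (0.0, 0.0), (50.0, 50.0)),
                make_record(1, (3.0, 4.0), (50.0, 50.0))]
        v = velocities(recs, "head", cal)
        assert v.values[0] == pytest.approx(5 * 0.2 / 1.0)
        assert velocities(recs, "tail", cal).values[0] == 0.0

    def test_transitions_touching_carried_frames_are_absent(self, cal):
        recs = [make_record(0, (0, 0), (9, 9)),
                make_record(1, (1, 0), (9, 9), status="carried_forward"),
                make_record(2, (2, 0), (9, 9)),
                make_record(3, (3, 0), (9, 9))]
        v = velocities(recs, "head", cal).values
        assert np.isnan(v[0]) and np.isnan(v[1])
        assert v[2] == pytest.approx(0.2)

    def test_window_average_smooths_but_defaults_off(self, cal):
        recs = [make_record(i, (float(i * i), 0.0), (0.0, 0.0))
                for i in range(6)]
        raw = velocities(recs, "head", cal).values
        smooth = velocities(recs, "head", cal, smooth_window=3).values
        assert smooth[2] == pytest.approx(raw[1:4].mean())
        assert not np.allclose(raw, smooth)

    def test_requires_two_records(self, cal):
        with pytest.raises(ValueError):
            velocities([make_record(0, (0, 0), (1, 1))], "head", cal)

    def test_reversed_sequence_gives_reversed_speeds(self, cal, rng):
        recs = [make_record(i, tuple(rng.uniform(0, 100, 2)),
                            tuple(rng.uniform(0, 100, 2))) for i in range(10)]
        fwd = velocities(recs, "head", cal).values
        rev_recs = [make_record(i, r.head_xy, r.tail_xy)
                    for i, r in enumerate(reversed(recs))]
        rev = velocities(rev_recs, "head", cal).values
        assert np.allclose(rev, fwd[::-1])


class TestSummarize:
    def test_basic_statistics(self):
        s = summarize([1.0, 2.0, 3.0])
        assert (s.mean, s.max, s.min) == (2.0, 3.0, 1.0)
        assert s.sd == pytest.approx(1.0)  # sample convention

    def test_single_value(self):
        s = summarize([5.0])
        assert (s.mean, s.sd, s.max, s.min) == (5.0, 0.0, 5.0, 5.0)

    def test_seeded_normal_draws_recover_parameters(self, rng):
        draws = rng.normal(3.0, 0.5, size=1000)
        s = summarize(draws)
        se_mean = 0.5 / math.sqrt(1000)
        assert abs(s.mean - 3.0) < 3 * se_mean
        assert abs(s.sd - 0.5) < 3 * 0.5 / math.sqrt(2 * 999)

    def test_all_absent_errors(self):
        with pytest.raises(ValueError):
            summarize([float("nan")])


class TestCompareTrajectories:
    def test_identical_trajectories(self, cal):
        recs = [make_record(i, (float(i), 2.0 * i), (0.0, float(i)),
                            center=(i / 2, i / 3)) for i in range(6)]
        stats = compare_trajectories(recs, recs, cal)
        for lab in ("head", "center", "tail"):
            assert stats[lab].pearson_r_x == pytest.approx(1.0)
            assert stats[lab].pearson_r_y == pytest.approx(1.0)
            assert stats[lab].mean_velocity_diff == pytest.approx(0.0)

    def test_negated_series_anticorrelates(self, cal):
        auto = [make_record(i, (float(i * i), 1.0), (0.0, 0.0)) for i in range(6)]
        ref = [make_record(i, (100.0 - i * i, 1.0), (0.0, 0.0)) for i in range(6)]
        stats = compare_trajectories(auto, ref, cal)
        assert stats["head"].pearson_r_x == pytest.approx(-1.0)

    def test_matches_textbook_formula_on_small_series(self, cal):
        xs_a = [1.0, 3.0, 2.0, 5.0, 4.0]
        xs_b = [2.0, 2.5, 3.0, 4.5, 5.0]
        auto = [make_record(i, (x, 0.0), (0.0, 0.0)) for i, x in enumerate(xs_a)]
        ref = [make_record(i, (x, 0.0), (0.0, 0.0)) for i, x in enumerate(xs_b)]
        r = compare_trajectories(auto, ref, cal)["head"].pearson_r_x
        ma, mb = sum(xs_a) / 5, sum(xs_b) / 5
        cov = sum((a - ma) * (b - mb) for a, b in zip(xs_a, xs_b))
        sa = math.sqrt(sum((a - ma) ** 2 for a in xs_a))
        sb = math.sqrt(sum((b - mb) ** 2 for b in xs_b))
        assert r == pytest.approx(cov / (sa * sb))

    def test_frame_mismatch_lists_missing(self, cal):
        auto = [make_record(i, (1.0, 1.0), (0.0, 0.0)) for i in range(4)]
        ref = [make_record(i, (1.0, 1.0), (0.0, 0.0)) for i in (0, 1, 3)]
        with pytest.raises(ValueError, match=r"\[2\]"):
            compare_trajectories(auto, ref, cal)

    def test_center_skipped_when_absent_in_reference(self, cal):
        auto = [make_record(i, (float(i), 0.0), (0.0, float(i)),
                            center=(1.0, 1.0)) for i in range(4)]
        ref = [make_record(i, (float(i), 0.0), (0.0, float(i))) for i in range(4)]
        stats = compare_trajectories(auto, ref, cal)
        assert set(stats) == {"head", "tail"}


class TestReferenceStretch:
    def test_epigeic_species_stretch_range(self):
        # 220.38 - 145.33 mm for the larger, litter-dwelling species
        s = REFERENCE_BODY_LENGTH_MM["M. hilgendorfi"]
        assert stretch_range(s) == pytest.approx(75.05, abs=1e-9)

    def test_summaries_are_internally_consistent(self):
        for s in REFERENCE_BODY_LENGTH_MM.values():
            assert s.min < s.mean < s.max
            assert s.sd > 0


class TestLengthSeries:
    def test_carried_frames_excluded_from_summary(self, cal):
        recs = [make_record(0, (0, 0), (1, 1), length=10.0),
                make_record(1, (0, 0), (1, 1), length=12.0),
                make_record(2, (0, 0), (1, 1), length=12.0,
                            status="carried_forward"),
                make_record(3, (0, 0), (1, 1), length=14.0)]
        ls = length_series(recs)
        assert np.isnan(ls.values[2])
        assert ls.summary.mean == pytest.approx(12.0)
        assert ls.summary.max == 14.0 and ls.summary.min == 10.0
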