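"""The synthetic worm generator: pose model, rendering, ground truth."""

import math

import numpy as np
import pytest

from mimizutrack.imaging_io import load_frames, read_trajectory_csv
from mimizutrack.preprocessing import CircleROI, binarize, red_channel
from mimizutrack.synthetic_data import (
    ArcLengthPath,
    NoiseSpec,
    RenderSettings,
    WormModel,
    WormOutOfArenaError,
    arc_path,
    coil_path,
    default_arena,
    generate_sequence,
    preset,
    render_frame,
    simulate_pose,
    simulate_sequence,
    spiral_path,
)

import oracles


def _small_setup():
    """A small frame and worm so brute-force pixel oracles stay cheap."""
    settings = RenderSettings(shape=(90, 120))
    arena = CircleROI(center_xy=(59.5, 44.5), radius=42.0)
    model = WormModel(
        guide_path=arc_path(radius_mm=5.0, span_rad=2.4,
                            center_mm=(-1.0, 0.5), start_angle=0.7),
        rest_length_mm=6.0, stretch_amplitude=0.2, stretch_period_s=20.0,
        speed_mm_s=0.2, half_width_mm=0.5, start_offset_mm=7.2,
    )
    return settings, arena, model


class TestStretchModel:
    def test_zero_amplitude_keeps_rest_length(self):
        _, _, model = _small_setup()
        model.stretch_amplitude = 0.0
        for t in (0.0, 3.0, 11.5):
            assert model.length_at(t) == model.rest_length_mm

    def test_sin_peak_reaches_max_stretch(self):
        _, _, model = _small_setup()
        model.stretch_amplitude = 0.5
        t = model.stretch_period_s / 4
        assert model.length_at(t) == pytest.approx(1.5 * model.rest_length_mm)

    def test_amplitude_beyond_elastic_limit_rejected(self):
        with pytest.raises(ValueError):
            WormModel(guide_path=arc_path(10.0, 2.0), stretch_amplitude=0.6)

    def test_discretized_centerline_length_matches_model(self):
        settings, arena, model = _small_setup()
        for t in (0.0, 2.0, 7.0):
            pose = simulate_pose(model, t, arena, settings)
            poly = np.hypot(*np.diff(pose.centerline_px, axis=0).T).sum()
            poly_mm = poly * settings.mm_per_pixel
            assert poly_mm == pytest.approx(model.length_at(t), rel=0.005)

    def test_center_is_arc_length_midpoint(self):
        settings, arena, model = _small_setup()
        pose = simulate_pose(model, 1.0, arena, settings)
        mid = model.guide_path(model.start_offset_mm + model.speed_mm_s
                               - model.length_at(1.0) / 2)
        expected = mid / settings.mm_per_pixel + np.array(arena.center_xy)
        assert pose.center_px == pytest.approx(tuple(expected))

    def test_pose_leaving_arena_rejected(self):
        settings = RenderSettings(shape=(90, 120))
        arena = CircleROI(center_xy=(59.5, 44.5), radius=20.0)  # tight dish
        model = WormModel(
            guide_path=arc_path(radius_mm=6.0, span_rad=3.0),
            rest_length_mm=10.0, stretch_amplitude=0.0, speed_mm_s=0.0,
            half_width_mm=0.5, start_offset_mm=10.0,
        )
        with pytest.raises(WormOutOfArenaError, match="out of arena"):
            simulate_pose(model, 0.0, arena, settings)


class TestRenderFrame:
    def test_noise_free_worm_matches_disk_union_oracle(self):
        settings, arena, model = _small_setup()
        pose = simulate_pose(model, 0.0, arena, settings)
        frame = render_frame(pose, model, arena, NoiseSpec(rate=0.0),
                             seed=0, settings=settings)
        worm = frame[:, :, 0] == settings.worm_rgb[0]
        hw_px = model.half_width_mm / settings.mm_per_pixel
        expected = oracles.polyline_disk_union(settings.shape,
                                               pose.centerline_px, hw_px)
        assert np.array_equal(worm, expected)

    def test_same_seed_reproduces_frame_exactly(self):
        settings, arena, model = _small_setup()
        pose = simulate_pose(model, 0.0, arena, settings)
        a = render_frame(pose, model, arena, NoiseSpec(rate=8.0), seed=5,
                         settings=settings)
        b = render_frame(pose, model, arena, NoiseSpec(rate=8.0), seed=5,
                         settings=settings)
        assert np.array_equal(a, b)

    def test_red_contrast_lets_auto_threshold_recover_worm(self):
        settings, arena, model = _small_setup()
        pose = simulate_pose(model, 0.0, arena, settings)
        frame = render_frame(pose, model, arena, NoiseSpec(rate=0.0),
                             seed=0, settings=settings)
        stamped = frame[:, :, 0] == settings.worm_rgb[0]
        mask = binarize(red_channel(frame), "auto", "dark_object",
                        roi_mask=arena.mask(settings.shape))
        recovered = (mask & stamped).sum() / stamped.sum()
        assert recovered >= 0.95

    def test_specks_stay_below_fragment_threshold(self):
        settings, arena, model = _small_setup()
        noise = NoiseSpec(rate=6.0)
        max_area = math.pi * noise.max_radius_px ** 2 + 8
        assert max_area < 50


class TestSequences:
    def test_zero_speed_keeps_head_fixed(self):
        settings, arena, model = _small_setup()
        model.speed_mm_s = 0.0
        model.stretch_amplitude = 0.0
        _, truth = simulate_sequence(model, 10, arena=arena,
                                     noise=NoiseSpec(rate=0.0), seed=2,
                                     settings=settings)
        assert len({t.head_xy for t in truth}) == 1

    def test_truth_length_follows_stretch_model(self):
        settings, arena, model = _small_setup()
        _, truth = simulate_sequence(model, 8, arena=arena,
                                     noise=NoiseSpec(rate=0.0), seed=2,
                                     settings=settings)
        for i, t in enumerate(truth):
            assert t.length_mm == pytest.approx(model.length_at(float(i)))

    def test_fixed_seed_gives_bitwise_identical_sequences(self):
        settings, arena, model = _small_setup()
        s1, _ = simulate_sequence(model, 5, arena=arena, seed=9,
                                  settings=settings)
        s2, _ = simulate_sequence(model, 5, arena=arena, seed=9,
                                  settings=settings)
        assert all(np.array_equal(a, b) for a, b in zip(s1.frames, s2.frames))

    def test_generate_sequence_writes_loadable_artifacts(self, tmp_path):
        settings, arena, model = _small_setup()
        out = tmp_path / "seq"
        generate_sequence(model, 4, arena=arena, noise=NoiseSpec(rate=2.0),
                          seed=1, out_dir=str(out), settings=settings)
        seq = load_frames(str(out), interval=1.0)
        assert len(seq) == 4 and seq.height == 90
        truth = read_trajectory_csv(str(out / "ground_truth.csv"))
        assert len(truth) == 4
        cfg_text = (out / "track_config.txt").read_text()
        assert "mm_per_pixel=0.2" in cfg_text and "roi=" in cfg_text


class TestPathsAndPresets:
    def test_arc_length_parameterization_is_uniform(self):
        path = spiral_path()
        s = np.linspace(0, path.total_length, 200)
        pts = path(s)
        steps = np.hypot(*np.diff(pts, axis=0).T)
        assert np.allclose(steps, steps[0], rtol=0.02)

    def test_coil_path_self_crosses(self):
        path = coil_path()
        pts = path(np.linspace(0, path.total_length, 3000))
        # the loop re-crosses the lead-in: some far-apart arc positions
        # nearly coincide in the plane
        d = np.hypot(pts[:, 0][:, None] - pts[:, 0], pts[:, 1][:, None] - pts[:, 1])
        i, j = np.meshgrid(np.arange(len(pts)), np.arange(len(pts)), indexing="ij")
        far_apart = np.abs(i - j) > 300
        assert (d[far_apart] < 0.2).any()

    @pytest.mark.parametrize("name", ["crawl", "static", "coil"])
    def test_presets_simulate_cleanly(self, name):
        model, arena, noise = preset(name)
        seq, truth = simulate_sequence(model, 2, arena=arena, noise=noise,
                                       seed=0)
        assert len(seq) == 2
        assert truth[0].length_mm > 0

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            preset("gallop")
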