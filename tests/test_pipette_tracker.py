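import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bfprobe.pipette_tracker import (
    DegenerateTemplateError,
    PipettePattern,
    UnrecoverablePatternError,
    ncc_match,
    recover_pattern,
    subpixel_peak,
    track_pipette,
)
from bfprobe.synthetic import BeadSceneSpec, PipetteSceneSpec, SceneConfig, render_scene
from bfprobe.video_io import open_video

from conftest import tip_pattern, write_tiff


class TestNCC:
    def test_verbatim_cutout_peaks_at_one(self):
        rng = np.random.default_rng(0)
        region = rng.uniform(0, 1, (40, 50))
        template = region[10:25, 20:35].copy()
        surface = ncc_match(region, template)
        i, j = np.unravel_index(np.argmax(surface), surface.shape)
        assert (i, j) == (10, 20)
        assert surface[i, j] == pytest.approx(1.0, abs=1e-9)

    def test_inverted_copy_anticorrelates(self):
        rng = np.random.default_rng(1)
        template = rng.uniform(0, 1, (9, 9))
        surface = ncc_match(1.0 - template, template)
        assert surface[0, 0] == pytest.approx(-1.0, abs=1e-9)

    def test_noisy_shifted_copy_peaks_at_the_shift(self):
        rng = np.random.default_rng(2)
        template = rng.uniform(0, 1, (15, 15))
        region = rng.uniform(0, 1, (30, 30))
        region[2 : 2 + 15, 3 : 3 + 15] = template + rng.normal(0, 0.05, (15, 15))
        surface = ncc_match(region, template)
        i, j = np.unravel_index(np.argmax(surface), surface.shape)
        assert (i, j) == (2, 3)

    def test_flat_template_rejected(self):
        with pytest.raises(DegenerateTemplateError):
            ncc_match(np.random.default_rng(0).uniform(0, 1, (20, 20)), np.ones((5, 5)))

    def test_values_bounded(self):
        rng = np.random.default_rng(3)
        surface = ncc_match(rng.uniform(0, 1, (25, 25)), rng.uniform(0, 1, (7, 7)))
        assert surface.min() >= -1.0 and surface.max() <= 1.0


class TestSubpixelPeak:
    @staticmethod
    def _paraboloid(x0, y0, a=1.0, d=-1.0, e=-1.0):
        xs = np.arange(-2, 3, dtype=float)
        X, Y = np.meshgrid(xs, xs)
        return a + d * (X - x0) ** 2 + e * (Y - y0) ** 2

    def test_symmetric_patch_gives_zero_offset(self):
        surface = self._paraboloid(0.0, 0.0)
        dx, dy, flag = subpixel_peak(surface, (2, 2))
        assert flag == "ok"
        assert (dx, dy) == (0.0, 0.0)

    def test_analytic_vertex_recovered_exactly(self):
        surface = self._paraboloid(0.3, -0.2)
        dx, dy, flag = subpixel_peak(surface, (2, 2))
        assert flag == "ok"
        assert dx == pytest.approx(0.3, abs=1e-9)
        assert dy == pytest.approx(-0.2, abs=1e-9)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        x0=st.floats(-0.49, 0.49),
        y0=st.floats(-0.49, 0.49),
        d=st.floats(-5.0, -0.05),
        e=st.floats(-5.0, -0.05),
        a=st.floats(-2.0, 2.0),
    )
    def test_any_sampled_elliptical_paraboloid_is_exact(self, x0, y0, d, e, a):
        surface = self._paraboloid(x0, y0, a=a, d=d, e=e)
        dx, dy, flag = subpixel_peak(surface, (2, 2))
        assert flag == "ok"
        assert dx == pytest.approx(x0, abs=1e-9)
        assert dy == pytest.approx(y0, abs=1e-9)

    def test_flat_patch_flags_degenerate(self):
        dx, dy, flag = subpixel_peak(np.ones((5, 5)), (2, 2))
        assert (dx, dy, flag) == (0.0, 0.0, "degenerate")

    def test_border_peak_flags_border(self):
        dx, dy, flag = subpixel_peak(np.eye(5), (0, 0))
        assert (dx, dy, flag) == (0.0, 0.0, "border")

    def test_offsets_clamped_inside_unit_cell(self):
        rng = np.random.default_rng(9)
        surface = rng.uniform(0, 1, (7, 7))
        i, j = np.unravel_index(np.argmax(surface[1:-1, 1:-1]), (5, 5))
        dx, dy, _ = subpixel_peak(surface, (i + 1, j + 1))
        assert abs(dx) < 1.0 and abs(dy) < 1.0


class TestRecovery:
    def test_defocused_frame_favours_some_variant(self, interrupted_scene):
        """On a blurred frame a dilated/eroded variant beats the original."""
        source, truth, config = interrupted_scene
        pattern = tip_pattern(source, truth)
        problem = source.get_frame(min(config.defocus_frames) + 5)
        from bfprobe.pipette_tracker import _best_match

        m_orig, _, _ = _best_match(problem.intensity, pattern.template)
        variant, detection = recover_pattern(
            source.get_frame(0), pattern, problem, threshold=0.95
        )
        assert detection.metric >= m_orig

    def test_identical_frame_keeps_original_pattern(self, basic_scene):
        source, truth, _ = basic_scene
        pattern = tip_pattern(source, truth)
        variant, detection = recover_pattern(
            source.get_frame(0), pattern, source.get_frame(0), threshold=0.95
        )
        assert variant.pattern_id == pattern.pattern_id
        assert detection.metric == pytest.approx(1.0, abs=1e-6)
        assert detection.flag == "recovered"

    def test_broken_pattern_is_unrecoverable(self, basic_scene):
        source, truth, _ = basic_scene
        rng = np.random.default_rng(13)
        bogus = PipettePattern(
            template=rng.uniform(0, 1, (20, 20)),
            source_frame=0,
            rect_xy_wh=(5, 5, 20, 20),
            pattern_id="bogus",
        )
        with pytest.raises(UnrecoverablePatternError):
            recover_pattern(source.get_frame(0), bogus, source.get_frame(1))


class TestTracking:
    def _scene(self, tmp_path, trajectory, n, noise=0.01, stem="pip"):
        config = SceneConfig(
            n_frames=n,
            pipette=PipetteSceneSpec(trajectory=trajectory),
            bead=BeadSceneSpec(),
            noise_sd=noise,
        )
        frames, truth = render_scene(config)
        source = open_video(write_tiff(tmp_path / f"{stem}.tif", frames))
        return source, truth

    def test_sinusoidal_motion_tracked_below_fifth_of_pixel(self, tmp_path):
        n = 100
        t = np.arange(n)
        traj = np.column_stack([60.0 + 5.0 * np.sin(2 * np.pi * t / 60.0), np.full(n, 60.0)])
        source, truth = self._scene(tmp_path, traj, n)
        track = track_pipette(source, range(n), tip_pattern(source, truth))
        assert not track.aborted and not track.failed_frames
        err = np.abs(track.positions - truth.anchor_xy)
        assert err.max() < 0.2

    def test_static_scene_constant_track_high_metric(self, tmp_path):
        traj = np.tile([60.0, 60.0], (20, 1))
        source, truth = self._scene(tmp_path, traj, 20, noise=0.0, stem="static")
        track = track_pipette(source, range(20), tip_pattern(source, truth))
        assert np.ptp(track.positions[:, 0]) == pytest.approx(0.0, abs=1e-9)
        assert track.metrics.min() > 0.999

    def test_slow_drift_is_followed_continuously(self, tmp_path):
        n = 80
        traj = np.column_stack([55.0 + 0.5 * np.arange(n), np.full(n, 60.0)])
        source, truth = self._scene(tmp_path, traj, n, stem="drift")
        track = track_pipette(source, range(n), tip_pattern(source, truth))
        assert not track.aborted
        err = np.abs(track.positions - truth.anchor_xy)
        assert err.max() < 0.3
        steps = np.diff(track.positions[:, 0])
        assert np.all(np.abs(steps - 0.5) < 0.3)  # no jumps, no stalls

    def test_pattern_round_trips_through_dict(self, basic_scene):
        source, truth, _ = basic_scene
        pattern = tip_pattern(source, truth)
        clone = PipettePattern.from_dict(pattern.to_dict())
        np.testing.assert_array_equal(clone.template, pattern.template)
        assert clone.anchor_offset_xy == pattern.anchor_offset_xy
        assert clone.rect_xy_wh == pattern.rect_xy_wh
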