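import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bfprobe.bead_tracker import (
    BeadSpec,
    Candidate,
    hough_circles,
    score_candidates,
    track_bead,
)
from bfprobe.synthetic import BeadSceneSpec, SceneConfig, render_scene
from bfprobe.video_io import open_video

from conftest import write_tiff


def _disc_patch(cx=24.3, cy=23.7, r=12.0, size=49, noise=0.0, seed=0, occlude=None):
    """Dark anti-aliased disc on a bright field, optionally occluded."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dist = np.hypot(xx - cx, yy - cy)
    img = 0.85 - 0.55 * np.clip(0.5 + (r - dist), 0, 1)
    if occlude is not None:
        x0, y0, w, h = occlude
        img[y0 : y0 + h, x0 : x0 + w] = 0.85
    if noise:
        img += np.random.default_rng(seed).normal(0, noise, img.shape)
    return np.clip(img, 0, 1)


class TestHoughCircles:
    def test_clean_disc_localized_to_half_pixel(self):
        patch = _disc_patch(noise=0.01)
        candidates = hough_circles(patch, 9, 15)
        best = candidates[0]
        assert abs(best.centre_xy[0] - 24.3) < 0.5
        assert abs(best.centre_xy[1] - 23.7) < 0.5
        assert abs(best.radius_px - 12.0) <= 1.0
        assert best.raw_score > 1.0

    def test_half_occluded_disc_still_found_with_reduced_score(self):
        clean = hough_circles(_disc_patch(), 9, 15)[0]
        # rectangle over the right half of the rim (> 50% of the edge hidden)
        occluded = hough_circles(_disc_patch(occlude=(22, 0, 27, 49)), 9, 15)[0]
        assert abs(occluded.centre_xy[0] - 24.3) < 1.0
        assert abs(occluded.centre_xy[1] - 23.7) < 1.0
        assert occluded.raw_score < clean.raw_score

    def test_blank_patch_yields_nothing(self):
        assert hough_circles(np.full((49, 49), 0.85), 9, 15) == []
        noise_only = np.clip(
            0.85 + np.random.default_rng(0).normal(0, 0.01, (49, 49)), 0, 1
        )
        for cand in hough_circles(noise_only, 9, 15):
            assert cand.raw_score < 0.5  # misses never look like detections


class TestScoreCandidates:
    def _cand(self, x, y, r=12.0, raw=1.0):
        return Candidate(centre_xy=(x, y), radius_px=r, raw_score=raw)

    def test_near_candidates_are_unpenalized(self):
        scored = score_candidates([self._cand(103.0, 100.0, raw=1.1)], (100.0, 100.0), 9.0)
        assert scored[0].distance_factor == 1.0
        assert scored[0].score == pytest.approx(1.1)

    def test_distance_factor_direct_substitution(self):
        # d = 2 * R_< with raw score 1.2 halves the score
        scored = score_candidates([self._cand(118.0, 100.0, raw=1.2)], (100.0, 100.0), 9.0)
        assert scored[0].distance_factor == pytest.approx(2.0)
        assert scored[0].score == pytest.approx(0.6)

    def test_equal_scores_break_toward_nearer_candidate(self):
        near = self._cand(104.0, 100.0, raw=1.0)
        far = self._cand(100.0, 92.0, raw=1.0)
        scored = score_candidates([far, near], (100.0, 100.0), 9.0)
        assert scored[0].centre_xy == (104.0, 100.0)

    def test_floor_drops_weak_candidates_before_scoring(self):
        weak = self._cand(100.0, 100.0, raw=0.1)
        ok = self._cand(105.0, 100.0, raw=0.9)
        scored = score_candidates([weak, ok], (100.0, 100.0), 9.0, candidate_floor=0.3)
        assert len(scored) == 1 and scored[0].raw_score == 0.9

    def test_empty_input_empty_output(self):
        assert score_candidates([], (0.0, 0.0), 9.0) == []

    def test_matches_direct_evaluation_on_enumerated_sets(self):
        """Oracle: recompute max(d_i, R_<)/R_< weighting by hand per candidate."""
        rng = np.random.default_rng(21)
        r_min = 8.0
        last = (50.0, 50.0)
        for _ in range(50):
            cands = [
                self._cand(
                    rng.uniform(30, 70), rng.uniform(30, 70), raw=rng.uniform(0.3, 2.0)
                )
                for _ in range(rng.integers(1, 8))
            ]
            scored = score_candidates(cands, last, r_min, candidate_floor=0.0)
            expected = []
            for c in cands:
                d = np.hypot(c.centre_xy[0] - last[0], c.centre_xy[1] - last[1])
                expected.append(c.raw_score / (max(d, r_min) / r_min))
            assert scored[0].score == pytest.approx(max(expected), rel=1e-12)
            assert [c.score for c in scored] == sorted(
                (c.score for c in scored), reverse=True
            )

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        raw=st.floats(0.3, 3.0),
        d1=st.floats(0.0, 40.0),
        d2=st.floats(0.0, 40.0),
    )
    def test_monotone_distance_penalty(self, raw, d1, d2):
        """For a fixed raw score, moving farther never raises the final score."""
        lo, hi = sorted((d1, d2))
        s_near = score_candidates(
            [self._cand(100.0 + lo, 100.0, raw=raw)], (100.0, 100.0), 9.0, 0.0
        )[0].score
        s_far = score_candidates(
            [self._cand(100.0 + hi, 100.0, raw=raw)], (100.0, 100.0), 9.0, 0.0
        )[0].score
        assert s_far <= s_near + 1e-12


class TestTrackBead:
    def test_linear_motion_tracked_without_failures(self, tmp_path):
        n = 100
        traj = np.column_stack([100.0 + 0.2 * np.arange(n), np.full(n, 60.0)])
        config = SceneConfig(n_frames=n, bead=BeadSceneSpec(trajectory=traj))
        frames, truth = render_scene(config)
        source = open_video(write_tiff(tmp_path / "lin.tif", frames))
        track = track_bead(source, range(n), BeadSpec(9, 15, tuple(truth.bead_xy[0])))
        assert not track.aborted and not track.failed_frames
        err = np.linalg.norm(track.positions - truth.bead_xy, axis=1)
        assert err.max() < 0.5

    def test_rmse_within_the_expected_precision_band(self, basic_tracks):
        """Well-contrasted beads localize to a few tens of nm at 0.1 um/px."""
        bead, _, truth = basic_tracks
        err = bead.positions - truth.bead_xy
        rmse = float(np.sqrt((err**2).sum(axis=1).mean()))
        assert rmse <= 0.5  # 50 nm at 0.1 um/px

    def test_vanishing_bead_aborts_after_five_failures(self, vanish_scene):
        source, truth = vanish_scene
        track = track_bead(source, range(80), BeadSpec(9, 15, tuple(truth.bead_xy[0])))
        assert track.aborted
        assert track.failed_frames == [50, 51, 52, 53, 54]
        assert track.detections[-1].frame == 54
        assert "frame 50" in track.abort_report

    def test_static_zero_noise_scene_gives_constant_track(self, tmp_path):
        config = SceneConfig(n_frames=10, noise_sd=0.0)
        frames, truth = render_scene(config)
        source = open_video(write_tiff(tmp_path / "static.tif", frames))
        track = track_bead(source, range(10), BeadSpec(9, 15, tuple(truth.bead_xy[0])))
        assert np.ptp(track.positions, axis=0) == pytest.approx((0.0, 0.0), abs=1e-12)
        assert np.ptp(track.metrics) == pytest.approx(0.0, abs=1e-12)

    def test_translation_equivariance(self, tmp_path):
        """Shifting the whole scene by an integer offset shifts the track."""
        n, offset = 12, np.array([7.0, 4.0])
        traj = np.column_stack([100.0 + 0.3 * np.arange(n), np.full(n, 55.0)])
        tracks = []
        for k, shift in enumerate((np.zeros(2), offset)):
            config = SceneConfig(
                n_frames=n, bead=BeadSceneSpec(trajectory=traj + shift), noise_sd=0.0
            )
            frames, truth = render_scene(config)
            source = open_video(write_tiff(tmp_path / f"shift{k}.tif", frames))
            tracks.append(
                track_bead(source, range(n), BeadSpec(9, 15, tuple(truth.bead_xy[0])))
            )
        delta = tracks[1].positions - tracks[0].positions
        np.testing.assert_allclose(delta, np.tile(offset, (n, 1)), atol=0.1)

    def test_seed_outside_frame_rejected(self, basic_scene):
        source, _, _ = basic_scene
        with pytest.raises(ValueError, match="outside frame"):
            track_bead(source, range(5), BeadSpec(9, 15, (1000.0, 10.0)))
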