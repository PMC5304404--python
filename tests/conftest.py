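"""Shared fixtures: synthetic recordings rendered once per session.

All test inputs are generated by the scene renderer at run time; nothing
is loaded from disk except what the tests themselves write.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import numpy as np
import pytest
import tifffile

from bfprobe.bead_tracker import BeadSpec, track_bead
from bfprobe.pipette_tracker import PipettePattern, track_pipette
from bfprobe.synthetic import get_fixture, render_scene
from bfprobe.video_io import open_video


def write_tiff(path: Path, frames: np.ndarray, fps: float = 65.0, pixel_scale: float = 0.1):
    """Write frames as a multi-page TIFF with embedded metadata."""
    tifffile.imwrite(
        path,
        frames,
        photometric="minisblack",
        description=json.dumps({"fps": fps, "pixel_scale": pixel_scale}),
    )
    return path


def tip_pattern(source, truth, frame: int = 0, pattern_id: str = "p0") -> PipettePattern:
    """Cut the standard tip rectangle around the true anchor of one frame."""
    ax, ay = truth.anchor_xy[frame]
    rect = (int(ax) - 20, int(ay) - 14, 26, 29)
    return PipettePattern.from_frame(
        source.get_frame(frame),
        rect,
        anchor_offset_xy=(ax - rect[0], ay - rect[1]),
        pattern_id=pattern_id,
    )


@pytest.fixture(scope="session")
def fixtures_dir(tmp_path_factory) -> Path:
    return tmp_path_factory.mktemp("scenes")


@pytest.fixture(scope="session")
def basic_scene(fixtures_dir):
    """The clean 456-frame reference scene, rendered and written once."""
    config = get_fixture("basic")
    frames, truth = render_scene(config, out_dir=fixtures_dir, stem="basic")
    source = open_video(fixtures_dir / "basic.tif")
    return source, truth, config


@pytest.fixture(scope="session")
def basic_tracks(basic_scene):
    """Both trackers run over the full basic scene (shared by many tests)."""
    source, truth, config = basic_scene
    spec = BeadSpec(r_min=9, r_max=15, seed_xy=tuple(truth.bead_xy[0]))
    bead = track_bead(source, range(source.n_frames), spec)
    pipette = track_pipette(source, range(source.n_frames), tip_pattern(source, truth))
    return bead, pipette, truth


@pytest.fixture(scope="session")
def interrupted_scene(fixtures_dir):
    config = get_fixture("interrupted")
    frames, truth = render_scene(config, out_dir=fixtures_dir, stem="interrupted")
    source = open_video(fixtures_dir / "interrupted.tif")
    return source, truth, config


@pytest.fixture(scope="session")
def vanish_scene(fixtures_dir):
    """80 frames in which the bead disappears from frame 50 onward."""
    config = get_fixture("basic")
    config.n_frames = 80
    config.bead.trajectory = config.bead.trajectory[:80]
    config.pipette.trajectory = config.pipette.trajectory[:80]
    gone = copy.deepcopy(config)
    gone.bead.depth = 0.0
    with_bead, truth = render_scene(config)
    without_bead, _ = render_scene(gone)
    frames = np.concatenate([with_bead[:50], without_bead[50:]])
    path = write_tiff(fixtures_dir / "vanish.tif", frames)
    return open_video(path), truth
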