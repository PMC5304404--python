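"""Synthetic BFP scenes with exact ground truth.

Renders the two objects the trackers care about — a dark bead (disc with a
smoothed rim, the typical brightfield appearance of a micron-scale bead
slightly out of the focal plane) and a pipette tip (two parallel dark
channel walls ending at an opening; the anchor point sits on the axis at
the tip) — on a bright background, with sub-pixel trajectories, Gaussian
sensor noise, and optional per-frame events: defocus (Gaussian blur, which
drives the SD2 contrast metric down exactly as focus loss does in real
recordings) and an occluding rectangle (hides part of the bead rim, the
situation partial-circle Hough detection is supposed to survive).

Everything is deterministic given the seed, and the renderer writes plain
multi-page 8-bit TIFF plus a ground-truth CSV, so full-pipeline tests need
no external data.  The red blood cell itself is not rendered: only the
bead and pipette are tracked, the cell enters the model solely through the
stiffness formula.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

DEFAULT_FPS = 65.0
DEFAULT_PIXEL_SCALE = 0.1  # um/px
DEFAULT_NOISE_SD = 0.01
DEFAULT_SHAPE = (120, 200)  # (height, width)


@dataclass
class BeadSceneSpec:
    radius_px: float = 12.0
    depth: float = 0.55  # intensity drop of the disc below background
    rim_width: float = 1.0  # smooth-edge width in px
    trajectory: Optional[np.ndarray] = None  # (n, 2) sub-pixel centres (x, y)


@dataclass
class PipetteSceneSpec:
    bar_gap: float = 16.0  # centre-to-centre distance of the channel walls
    bar_thickness: float = 5.0
    depth: float = 0.5
    trajectory: Optional[np.ndarray] = None  # (n, 2) anchor positions (x, y)


@dataclass
class SceneConfig:
    n_frames: int
    fps: float = DEFAULT_FPS
    shape: Tuple[int, int] = DEFAULT_SHAPE
    pixel_scale: float = DEFAULT_PIXEL_SCALE
    background: float = 0.85
    bead: BeadSceneSpec = field(default_factory=BeadSceneSpec)
    pipette: PipetteSceneSpec = field(default_factory=PipetteSceneSpec)
    noise_sd: float = DEFAULT_NOISE_SD
    defocus_frames: Sequence[int] = ()
    defocus_blur_sd: float = 2.5
    occluder_rect: Optional[Tuple[int, int, int, int]] = None  # (x, y, w, h)
    occluder_frames: Sequence[int] = ()
    t0_frame: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        h, w = self.shape
        n = self.n_frames
        if self.bead.trajectory is None:
            self.bead.trajectory = np.tile([0.72 * w, 0.5 * h], (n, 1))
        if self.pipette.trajectory is None:
            self.pipette.trajectory = np.tile([0.30 * w, 0.5 * h], (n, 1))
        self.bead.trajectory = np.asarray(self.bead.trajectory, dtype=np.float64)
        self.pipette.trajectory = np.asarray(self.pipette.trajectory, dtype=np.float64)
        for name, traj in (("bead", self.bead.trajectory), ("pipette", self.pipette.trajectory)):
            if traj.shape != (n, 2):
                raise ValueError(f"{name} trajectory must have shape ({n}, 2), got {traj.shape}")
        if not (0 <= self.t0_frame < n):
            raise ValueError(f"t0_frame {self.t0_frame} outside [0, {n})")


@dataclass
class GroundTruth:
    """Per-frame true geometry of the rendered scene."""

    bead_xy: np.ndarray  # (n, 2)
    bead_radius_px: float
    anchor_xy: np.ndarray  # (n, 2)
    x_um: np.ndarray
    dx_um: np.ndarray
    t0_frame: int
    pixel_scale: float
    events: List[str] = field(default_factory=list)  # per-frame label, "" if none

    def to_frame(self):
        import pandas as pd

        n = self.bead_xy.shape[0]
        return pd.DataFrame(
            {
                "frame": np.arange(n),
                "bead_x": self.bead_xy[:, 0],
                "bead_y": self.bead_xy[:, 1],
                "r": self.bead_radius_px,
                "pip_x": self.anchor_xy[:, 0],
                "pip_y": self.anchor_xy[:, 1],
                "x_um": self.x_um,
                "dx_um": self.dx_um,
                "event": self.events,
            }
        )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _render_frame(config: SceneConfig, i: int, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    img = np.full(config.shape, config.background, dtype=np.float64)
    # pipette: two horizontal dark bars from the left edge to the tip x
    ax, ay = config.pipette.trajectory[i]
    p = config.pipette
    for side in (-1.0, 1.0):
        yc = ay + side * p.bar_gap / 2.0
        cov_y = np.clip(0.5 + (p.bar_thickness / 2.0 - np.abs(yy - yc)), 0.0, 1.0)
        cov_x = np.clip(0.5 + (ax - xx), 0.0, 1.0)
        img -= p.depth * cov_y * cov_x
    # bead: dark disc with a smoothed rim
    bx, by = config.bead.trajectory[i]
    b = config.bead
    dist = np.hypot(xx - bx, yy - by)
    cov = np.clip(0.5 + (b.radius_px - dist) / b.rim_width, 0.0, 1.0)
    img -= b.depth * cov
    # occluder erases everything under its rectangle back to background
    if config.occluder_rect is not None and i in set(config.occluder_frames):
        x, y, w, h = config.occluder_rect
        img[y : y + h, x : x + w] = config.background
    if i in set(config.defocus_frames):
        img = gaussian_filter(img, config.defocus_blur_sd, mode="nearest")
    return np.clip(img, 0.0, 1.0)


def render_scene(config: SceneConfig, out_dir=None, stem: str = "scene"):
    """Render all frames and assemble the ground truth.

    Deterministic given ``config.seed``.  Returns ``(frames, truth)`` with
    ``frames`` an (n, height, width) uint8 array.  With ``out_dir`` set, a
    multi-page TIFF (fps and pixel scale embedded as a JSON description)
    and a ground-truth CSV are written there and their paths attached as
    ``truth.tiff_path`` / ``truth.csv_path``.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    frames = np.empty((config.n_frames, h, w), dtype=np.uint8)
    events = []
    occ = set(config.occluder_frames) if config.occluder_rect is not None else set()
    dfc = set(config.defocus_frames)
    for i in range(config.n_frames):
        img = _render_frame(config, i, yy, xx)
        if config.noise_sd > 0:
            img = np.clip(img + rng.normal(0.0, config.noise_sd, img.shape), 0.0, 1.0)
        frames[i] = np.rint(img * 255.0).astype(np.uint8)
        tags = [name for name, members in (("defocus", dfc), ("occluder", occ)) if i in members]
        events.append("+".join(tags))
    x_um = (
        np.hypot(
            config.pipette.trajectory[:, 0] - config.bead.trajectory[:, 0],
            config.pipette.trajectory[:, 1] - config.bead.trajectory[:, 1],
        )
        * config.pixel_scale
    )
    truth = GroundTruth(
        bead_xy=config.bead.trajectory.copy(),
        bead_radius_px=config.bead.radius_px,
        anchor_xy=config.pipette.trajectory.copy(),
        x_um=x_um,
        dx_um=x_um - x_um[config.t0_frame],
        t0_frame=config.t0_frame,
        pixel_scale=config.pixel_scale,
        events=events,
    )
    if out_dir is not None:
        import tifffile

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tiff_path = out_dir / f"{stem}.tif"
        desc = json.dumps({"fps": config.fps, "pixel_scale": config.pixel_scale})
        tifffile.imwrite(tiff_path, frames, photometric="minisblack", description=desc)
        csv_path = out_dir / f"{stem}_truth.csv"
        truth.to_frame().to_csv(csv_path, index=False)
        truth.tiff_path = tiff_path  # type: ignore[attr-defined]
        truth.csv_path = csv_path  # type: ignore[attr-defined]
    return frames, truth


# ---------------------------------------------------------------------------
# standard fixtures
# ---------------------------------------------------------------------------

def _sinusoid(n: int, centre: Tuple[float, float], amp_x: float, period: float) -> np.ndarray:
    t = np.arange(n)
    x = centre[0] + amp_x * np.sin(2.0 * np.pi * t / period)
    y = np.full(n, centre[1])
    return np.column_stack([x, y])


def _ramp(n: int, start: Tuple[float, float], rate_xy: Tuple[float, float]) -> np.ndarray:
    t = np.arange(n)[:, None]
    return np.asarray(start, dtype=np.float64) + t * np.asarray(rate_xy, dtype=np.float64)


def standard_fixtures(seed: int = 0) -> Dict[str, SceneConfig]:
    """Named scene presets covering the canonical analysis situations.

    * ``basic`` — 456 frames at 65 fps, clean contrast, pipette swaying
      sinusoidally while the bead is slowly pulled away: a single-interval
      run whose force course ramps within the linear regime.
    * ``interrupted`` — one defocus episode mid-recording after which focus
      reverts, so one pipette pattern and one reference frame serve two
      intervals around the gap.
    * ``multiinterval`` — a long middle stretch at a *different* stable
      focus, trackable only with a locally cut pattern and manual force
      offset alignment, plus transition gaps.
    * ``occlusion`` — a rectangle hides more than half of the bead rim for
      a stretch of frames.
    * ``separation`` — the bead breaks away from the probe mid-recording
      (distance ramps up fast); the Delta_x spike is tracked faithfully but
      carries no physical meaning.
    """
    presets: Dict[str, SceneConfig] = {}

    n = 456
    presets["basic"] = SceneConfig(
        n_frames=n,
        seed=seed,
        bead=BeadSceneSpec(trajectory=_ramp(n, (142.0, 60.0), (0.008, 0.0))),
        pipette=PipetteSceneSpec(trajectory=_sinusoid(n, (60.0, 60.0), 1.0, 200.0)),
    )

    n = 300
    presets["interrupted"] = SceneConfig(
        n_frames=n,
        seed=seed + 1,
        bead=BeadSceneSpec(trajectory=_ramp(n, (142.0, 60.0), (0.01, 0.0))),
        pipette=PipetteSceneSpec(trajectory=_sinusoid(n, (60.0, 60.0), 1.0, 160.0)),
        defocus_frames=range(120, 161),
        defocus_blur_sd=2.5,
    )

    n = 400
    presets["multiinterval"] = SceneConfig(
        n_frames=n,
        seed=seed + 2,
        bead=BeadSceneSpec(trajectory=_ramp(n, (142.0, 60.0), (0.008, 0.0))),
        pipette=PipetteSceneSpec(trajectory=_sinusoid(n, (60.0, 60.0), 1.0, 220.0)),
        # stable alternative focus over the middle stretch; the frames just
        # inside its edges are conventionally excluded as transitions
        defocus_frames=range(140, 260),
        defocus_blur_sd=1.8,
    )

    n = 200
    occ_x = int(142 - 2)  # covers the right half of the bead rim
    presets["occlusion"] = SceneConfig(
        n_frames=n,
        seed=seed + 3,
        bead=BeadSceneSpec(trajectory=_ramp(n, (142.0, 60.0), (0.0, 0.0))),
        pipette=PipetteSceneSpec(trajectory=_sinusoid(n, (60.0, 60.0), 1.0, 120.0)),
        occluder_rect=(occ_x, 40, 40, 40),
        occluder_frames=range(80, 121),
    )

    n = 200
    sep = _ramp(n, (130.0, 60.0), (0.0, 0.0))
    t = np.arange(n)
    run = np.clip(t - 100, 0, 30)  # departs at frame 100, 1 px/frame for 30 frames
    sep[:, 0] += run * 1.0
    presets["separation"] = SceneConfig(
        n_frames=n,
        seed=seed + 4,
        bead=BeadSceneSpec(trajectory=sep),
        pipette=PipetteSceneSpec(trajectory=_sinusoid(n, (55.0, 60.0), 1.0, 120.0)),
    )
    return presets


def get_fixture(name: str, seed: int = 0) -> SceneConfig:
    presets = standard_fixtures(seed)
    try:
        return presets[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        ) from None
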