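"""Probe-bead tracking by circular Hough transform with distance weighting.

The bead is a dark disc of roughly known radius.  Each frame, a region of
interest around the last confirmed centre is searched for circle candidates
by *two* gradient-voting Hough variants whose candidate lists are pooled:

* a two-stage accumulator (one 2-D vote array per trial radius, the radius
  read off the winning layer), and
* a phase-coding accumulator (a single complex 2-D array over the whole
  radius range; the vote weight encodes the trial radius and the radius is
  decoded from the phase at the peak).

Votes are cast along each edge pixel's intensity gradient, so only centres
the rim normals converge on accumulate.  That tolerates partial occlusion
of the rim — votes thin out but the peak survives and is not displaced, as
it would be if whole circles voted.  Candidates are scored by their
accumulator value divided by a distance factor
``f_i = max(d_i, R_<) / R_<`` that penalizes candidates further than one
minimum-radius from the previous position; the winner's score is the bead
metric M_b.  Frames whose best score stays below the metric threshold
after adaptive refinement are flagged and logged, and tracking proceeds;
a run of consecutive frames with nothing recognizable at all aborts the
track with a report naming the first bad frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage.feature import canny, peak_local_max

DEFAULT_METRIC_THRESHOLD = 0.8
DEFAULT_CANDIDATE_FLOOR = 0.3
DEFAULT_SENSITIVITY = 0.85
DEFAULT_MAX_CONSECUTIVE_FAILURES = 5
#: sensitivity increment applied by adaptive refinement
SENSITIVITY_STEP = 0.05


@dataclass(frozen=True)
class BeadSpec:
    """Detection parameters for one tracked bead."""

    r_min: float  # smallest admissible candidate radius R_< (px)
    r_max: float  # largest admissible candidate radius R_> (px)
    seed_xy: Tuple[float, float]  # initial centre position
    metric_threshold: float = DEFAULT_METRIC_THRESHOLD
    candidate_floor: float = DEFAULT_CANDIDATE_FLOOR
    sensitivity: float = DEFAULT_SENSITIVITY
    max_consecutive_failures: int = DEFAULT_MAX_CONSECUTIVE_FAILURES

    def __post_init__(self) -> None:
        if not 0 < self.r_min < self.r_max:
            raise ValueError(f"need 0 < r_min < r_max, got ({self.r_min}, {self.r_max})")
        if not self.metric_threshold > 0:
            raise ValueError("metric_threshold must be positive")
        if self.max_consecutive_failures < 1:
            raise ValueError("max_consecutive_failures must be >= 1")


@dataclass
class Candidate:
    centre_xy: Tuple[float, float]
    radius_px: float
    raw_score: float  # accumulator value M_b,i
    distance: float = np.nan  # d_i from last confirmed centre
    distance_factor: float = 1.0  # f_i = max(d_i, R_<)/R_<
    score: float = np.nan  # M_b,i / f_i


@dataclass
class BeadDetection:
    frame: int
    centre_xy: Tuple[float, float]
    radius_px: float
    metric: float  # M_b (winning distance-weighted score)
    raw_metric: float  # accumulator value of the winner
    distance_factor: float
    flag: str  # ok | refined | low_metric | failed


@dataclass
class BeadTrack:
    detections: List[BeadDetection] = field(default_factory=list)
    failed_frames: List[int] = field(default_factory=list)
    aborted: bool = False
    abort_report: str = ""

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections], dtype=int)

    @property
    def positions(self) -> np.ndarray:
        return np.array([d.centre_xy for d in self.detections], dtype=np.float64)

    @property
    def radii(self) -> np.ndarray:
        return np.array([d.radius_px for d in self.detections], dtype=np.float64)

    @property
    def metrics(self) -> np.ndarray:
        return np.array([d.metric for d in self.detections], dtype=np.float64)

    @property
    def last_confirmed_centre(self) -> Optional[Tuple[float, float]]:
        for det in reversed(self.detections):
            if det.flag in ("ok", "refined"):
                return det.centre_xy
        return None


# ---------------------------------------------------------------------------
# Hough variants
# ---------------------------------------------------------------------------

def _edge_map(patch: np.ndarray, sensitivity: float) -> np.ndarray:
    """Canny edges; higher sensitivity lowers the hysteresis thresholds."""
    high = max(0.02, 0.5 * (1.0 - sensitivity))
    return canny(patch, sigma=1.0, low_threshold=0.4 * high, high_threshold=high)


def _refine_peak_centroid(layer: np.ndarray, i: int, j: int) -> Tuple[float, float]:
    """Sub-pixel centre: accumulator-weighted centroid of the 3x3 peak
    neighbourhood (background-subtracted so flanking votes do not drag the
    estimate toward the patch centre of mass)."""
    h, w = layer.shape
    if i <= 0 or j <= 0 or i >= h - 1 or j >= w - 1:
        return float(j), float(i)
    z = np.asarray(layer[i - 1 : i + 2, j - 1 : j + 2], dtype=np.float64)
    z = np.clip(z - z.min(), 0.0, None)
    tot = z.sum()
    if tot == 0.0:
        return float(j), float(i)
    g = np.array([-1.0, 0.0, 1.0])
    dx = float((z * g[None, :]).sum() / tot)
    dy = float((z * g[:, None]).sum() / tot)
    return j + dx, i + dy


def _pool_votes(layer: np.ndarray) -> np.ndarray:
    """3x3 box sum of an accumulator layer.

    A circle centred between pixels splits its votes over adjacent cells
    (and gradient noise scatters them by about a pixel); pooling makes the
    peak score the *total* local vote mass, insensitive to the sub-pixel
    phase of the true centre.
    """
    from scipy.ndimage import uniform_filter

    return uniform_filter(layer, size=3, mode="constant") * 9.0


def _gradient_votes(patch: np.ndarray, edges: np.ndarray):
    """Edge pixels and their unit gradient directions.

    Votes are cast along the intensity gradient (both senses, so dark and
    bright beads work alike): only centres that the rim normals converge on
    accumulate, which is what keeps a partially occluded arc from being
    explained by a shifted smaller circle.
    """
    ys, xs = np.nonzero(edges)
    if ys.size == 0:
        return None
    gy, gx = np.gradient(patch)
    ux, uy = gx[ys, xs], gy[ys, xs]
    norm = np.hypot(ux, uy)
    keep = norm > 1e-12
    if not keep.any():
        return None
    return (
        xs[keep].astype(np.float64),
        ys[keep].astype(np.float64),
        ux[keep] / norm[keep],
        uy[keep] / norm[keep],
    )


def _hough_variants(
    patch: np.ndarray, edges: np.ndarray, radii: np.ndarray, n_peaks: int
) -> List[Candidate]:
    """Candidates from both gradient-voting Hough variants, pooled.

    One vote pass feeds two accumulators: a per-radius stack (the
    *two-stage* variant: each trial radius keeps its own 2-D array, the
    radius is read off the winning layer) and a single complex array (the
    *phase-coding* variant: the vote weight ``exp(2*pi*1j*k/n_r)`` encodes
    the trial radius, votes at the true radius add coherently and the
    radius is decoded from the phase at the peak).  Scores are box-pooled
    over 3x3 and normalized by the ideal rim vote count ``2*pi*r``, so a
    clean fully visible rim scores about 1 and a half-occluded one about
    0.5, whichever variant found it.
    """
    votes = _gradient_votes(patch, edges)
    if votes is None:
        return []
    xs, ys, ux, uy = votes
    h, w = patch.shape
    acc_c = np.zeros((h, w), dtype=np.complex128)
    n_r = radii.size
    min_dist = max(2, int(radii[0] // 2))
    out: List[Candidate] = []
    for k, r in enumerate(radii):
        layer = np.zeros((h, w), dtype=np.float64)
        weight = np.exp(2j * np.pi * k / n_r)
        for sign in (1.0, -1.0):
            cx = np.rint(xs + sign * r * ux).astype(int)
            cy = np.rint(ys + sign * r * uy).astype(int)
            ok = (cx >= 0) & (cx < w) & (cy >= 0) & (cy < h)
            np.add.at(layer, (cy[ok], cx[ok]), 1.0)
        acc_c += layer * weight
        pooled = _pool_votes(layer) / (2.0 * np.pi * r)
        for i, j in peak_local_max(pooled, min_distance=min_dist, num_peaks=n_peaks):
            score = float(pooled[i, j])
            if score <= 0.0:
                continue
            cxy = _refine_peak_centroid(pooled, int(i), int(j))
            out.append(Candidate(centre_xy=cxy, radius_px=float(r), raw_score=score))
    # phase-coding variant: coherent pooling, radius decoded from the phase
    pooled_c = _pool_votes(acc_c.real) + 1j * _pool_votes(acc_c.imag)
    mag = np.abs(pooled_c)
    for i, j in peak_local_max(mag, min_distance=min_dist, num_peaks=n_peaks):
        phase = np.angle(pooled_c[i, j]) % (2.0 * np.pi)
        r_dec = float(radii[0]) + phase / (2.0 * np.pi) * n_r
        r_dec = float(np.clip(r_dec, radii[0], radii[-1]))
        score = float(mag[i, j] / (2.0 * np.pi * r_dec))
        if score <= 0.0:
            continue
        cxy = _refine_peak_centroid(mag, int(i), int(j))
        out.append(Candidate(centre_xy=cxy, radius_px=r_dec, raw_score=score))
    return out


def _dedup(candidates: List[Candidate], min_sep: float = 1.0) -> List[Candidate]:
    """Merge candidates with centres closer than ``min_sep``; keep the
    higher raw score."""
    kept: List[Candidate] = []
    for cand in sorted(candidates, key=lambda c: -c.raw_score):
        cx, cy = cand.centre_xy
        if all(
            np.hypot(cx - k.centre_xy[0], cy - k.centre_xy[1]) >= min_sep for k in kept
        ):
            kept.append(cand)
    return kept


def hough_circles(
    frame_region: np.ndarray,
    r_min: float,
    r_max: float,
    sensitivity: float = DEFAULT_SENSITIVITY,
    n_peaks: int = 5,
) -> List[Candidate]:
    """Circle candidates in a patch, pooled from both Hough variants.

    Returns candidates sorted by accumulator score (descending), centres
    refined to sub-pixel, duplicates within 1 px merged.  A flat patch or a
    patch without edges yields an empty list, never an exception.
    """
    patch = np.asarray(frame_region, dtype=np.float64)
    if patch.ndim != 2 or min(patch.shape) < 3 or patch.std() == 0.0:
        return []
    radii = np.arange(int(np.floor(r_min)), int(np.ceil(r_max)) + 1)
    edges = _edge_map(patch, sensitivity)
    if not edges.any():
        return []
    return _dedup(_hough_variants(patch, edges, radii, n_peaks))


# ---------------------------------------------------------------------------
# scoring and tracking
# ---------------------------------------------------------------------------

def score_candidates(
    candidates: List[Candidate],
    last_centre: Tuple[float, float],
    r_min: float,
    candidate_floor: float = DEFAULT_CANDIDATE_FLOOR,
) -> List[Candidate]:
    """Distance-weighted scores, sorted best first.

    ``f_i = max(d_i, R_<) / R_<`` leaves candidates within one minimum
    radius of the previous centre unpenalized and divides the accumulator
    score of farther ones by their distance in units of R_<.  Candidates
    below ``candidate_floor`` (raw accumulator value) are dropped before
    scoring.  Ties break toward the nearer candidate, then the larger
    radius.
    """
    lx, ly = last_centre
    scored: List[Candidate] = []
    for cand in candidates:
        if cand.raw_score < candidate_floor:
            continue
        d = float(np.hypot(cand.centre_xy[0] - lx, cand.centre_xy[1] - ly))
        f = max(d, r_min) / r_min
        scored.append(
            replace(cand, distance=d, distance_factor=f, score=cand.raw_score / f)
        )
    scored.sort(key=lambda c: (-c.score, c.distance, -c.radius_px))
    return scored


def _roi_bounds(centre, half, shape):
    cx, cy = centre
    h, w = shape
    x0 = max(0, int(round(cx - half)))
    y0 = max(0, int(round(cy - half)))
    x1 = min(w, int(round(cx + half)) + 1)
    y1 = min(h, int(round(cy + half)) + 1)
    return x0, y0, x1, y1


def _detect_in_roi(img, centre, half, spec: BeadSpec, sensitivity: float):
    x0, y0, x1, y1 = _roi_bounds(centre, half, img.shape)
    patch = img[y0:y1, x0:x1]
    cands = hough_circles(patch, spec.r_min, spec.r_max, sensitivity)
    for c in cands:
        c.centre_xy = (c.centre_xy[0] + x0, c.centre_xy[1] + y0)
    return score_candidates(cands, centre, spec.r_min, spec.candidate_floor)


def track_bead(source, interval: Sequence[int], spec: BeadSpec) -> BeadTrack:
    """Track one bead across an interval of frames.

    A square region of side ``4 * r_max`` centred on the last confirmed
    centre (the seed for the first frame) is searched each frame.  When the
    winning score falls below the metric threshold, refinement first grows
    the region by 50%, then raises the detector sensitivity one step; a
    frame that still fails is flagged and logged, and the previous centre
    is kept for the next frame.  ``max_consecutive_failures`` consecutive
    failures abort the track with a report naming the first bad frame.
    """
    frames = [int(i) for i in interval]
    if not frames:
        raise ValueError("empty interval")
    probe = source.get_frame(frames[0])
    h, w = probe.intensity.shape
    sx, sy = spec.seed_xy
    if not (0 <= sx < w and 0 <= sy < h):
        raise ValueError(f"bead seed {spec.seed_xy} outside frame {w}x{h}")
    track = BeadTrack()
    last_centre = (float(sx), float(sy))
    half = 2.0 * spec.r_max  # ROI side 4*r_max
    consecutive = 0
    for idx in frames:
        img = source.get_frame(idx).intensity
        scored = _detect_in_roi(img, last_centre, half, spec, spec.sensitivity)
        flag = "ok"
        if not scored or scored[0].score < spec.metric_threshold:
            # refinement 1: enlarge the ROI by 50%
            bigger = _detect_in_roi(img, last_centre, half * 1.5, spec, spec.sensitivity)
            if bigger and (not scored or bigger[0].score > scored[0].score):
                scored, flag = bigger, "refined"
        if not scored or scored[0].score < spec.metric_threshold:
            # refinement 2: raise the edge sensitivity one step
            hot = _detect_in_roi(
                img, last_centre, half * 1.5, spec,
                min(0.99, spec.sensitivity + SENSITIVITY_STEP),
            )
            if hot and (not scored or hot[0].score > scored[0].score):
                scored, flag = hot, "refined"
        if scored and scored[0].score >= spec.metric_threshold:
            win = scored[0]
            track.detections.append(
                BeadDetection(
                    frame=idx,
                    centre_xy=win.centre_xy,
                    radius_px=win.radius_px,
                    metric=win.score,
                    raw_metric=win.raw_score,
                    distance_factor=win.distance_factor,
                    flag=flag,
                )
            )
            last_centre = win.centre_xy
            consecutive = 0
        elif scored:
            # recognized but suspect: warn, log, proceed from the best guess
            best = scored[0]
            track.failed_frames.append(idx)
            track.detections.append(
                BeadDetection(
                    frame=idx,
                    centre_xy=best.centre_xy,
                    radius_px=best.radius_px,
                    metric=best.score,
                    raw_metric=best.raw_score,
                    distance_factor=best.distance_factor,
                    flag="low_metric",
                )
            )
            last_centre = best.centre_xy
            consecutive = 0
        else:
            # nothing recognizable at all: counts toward the abort limit
            track.failed_frames.append(idx)
            consecutive += 1
            track.detections.append(
                BeadDetection(
                    frame=idx,
                    centre_xy=(np.nan, np.nan),
                    radius_px=np.nan,
                    metric=0.0,
                    raw_metric=0.0,
                    distance_factor=np.nan,
                    flag="failed",
                )
            )
            if consecutive >= spec.max_consecutive_failures:
                track.aborted = True
                track.abort_report = (
                    f"bead lost: no recognizable candidate in {consecutive} "
                    f"consecutive frames starting at frame "
                    f"{track.failed_frames[-consecutive]}"
                )
                break
    return track
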