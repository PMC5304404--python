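"""Pipette-tip tracking by normalized cross-correlation template matching.

The pipette tip has a rich, stable intensity profile (two dark channel
walls converging on the opening), which makes template matching the method
of choice: a user-delineated rectangle from one frame is slid over a
restricted search region of every other frame, the normalized
cross-correlation surface is evaluated, and the integer-pixel peak is
refined by fitting an elliptical paraboloid to its 3x3 neighbourhood.
Because the correlation pools information from every template pixel, the
anchor localization is typically an order of magnitude more precise than
the bead's.

When the correlation drops (defocus, contrast change) the tracker first
re-searches a larger region, then rebuilds the template: variants of the
original rectangle dilated/eroded by a few pixels per side are cut from the
interval's initial frame and the best-matching variant takes over.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage.feature import match_template

DEFAULT_METRIC_THRESHOLD = 0.95
DEFAULT_MAX_CONSECUTIVE_FAILURES = 5
#: rectangle margin steps (px per side) for pattern dilation/erosion recovery
RECOVERY_MARGINS = (0, 2, -2, 4, -4)


class DegenerateTemplateError(ValueError):
    """Template with zero intensity variance cannot be matched."""


class UnrecoverablePatternError(RuntimeError):
    """Pattern no longer localizes even in the interval's initial frame."""


@dataclass
class PipettePattern:
    """Image template of the pipette tip plus its anchor point.

    The anchor is the physical reference point whose distance to the bead
    centre defines x(t); by default it sits at the template centre.
    """

    template: np.ndarray
    source_frame: int
    rect_xy_wh: Tuple[int, int, int, int]
    anchor_offset_xy: Optional[Tuple[float, float]] = None
    pattern_id: str = "pattern-0"

    def __post_init__(self) -> None:
        self.template = np.asarray(self.template, dtype=np.float64)
        h, w = self.template.shape
        if h < 3 or w < 3:
            raise ValueError(f"template must be at least 3x3, got {w}x{h}")
        if self.anchor_offset_xy is None:
            self.anchor_offset_xy = ((w - 1) / 2.0, (h - 1) / 2.0)
        ax, ay = self.anchor_offset_xy
        if not (0 <= ax <= w - 1 and 0 <= ay <= h - 1):
            raise ValueError(f"anchor offset {self.anchor_offset_xy} outside template {w}x{h}")

    @classmethod
    def from_frame(cls, frame, rect_xy_wh, anchor_offset_xy=None, pattern_id="pattern-0"):
        x, y, w, h = (int(v) for v in rect_xy_wh)
        patch = frame.intensity[y : y + h, x : x + w]
        return cls(
            template=patch.copy(),
            source_frame=frame.index,
            rect_xy_wh=(x, y, w, h),
            anchor_offset_xy=anchor_offset_xy,
            pattern_id=pattern_id,
        )

    def to_dict(self) -> dict:
        return {
            "pattern_id": self.pattern_id,
            "source_frame": int(self.source_frame),
            "rect_xy_wh": [int(v) for v in self.rect_xy_wh],
            "anchor_offset_xy": [float(v) for v in self.anchor_offset_xy],
            "template": self.template.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipettePattern":
        return cls(
            template=np.asarray(d["template"], dtype=np.float64),
            source_frame=int(d["source_frame"]),
            rect_xy_wh=tuple(d["rect_xy_wh"]),
            anchor_offset_xy=tuple(d["anchor_offset_xy"]),
            pattern_id=d.get("pattern_id", "pattern-0"),
        )


@dataclass
class PipetteDetection:
    frame: int
    anchor_xy: Tuple[float, float]
    metric: float  # M_p, max normalized cross-correlation
    pattern_id: str
    flag: str  # ok | low_metric | recovered | failed | border
    top_left_xy: Tuple[float, float] = (np.nan, np.nan)


@dataclass
class PipetteTrack:
    detections: List[PipetteDetection] = field(default_factory=list)
    failed_frames: List[int] = field(default_factory=list)
    aborted: bool = False
    abort_report: str = ""

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections], dtype=int)

    @property
    def positions(self) -> np.ndarray:
        return np.array([d.anchor_xy for d in self.detections], dtype=np.float64)

    @property
    def metrics(self) -> np.ndarray:
        return np.array([d.metric for d in self.detections], dtype=np.float64)


# ---------------------------------------------------------------------------
# matching primitives
# ---------------------------------------------------------------------------

def ncc_match(frame_region: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Normalized cross-correlation surface of template over a region.

    Entry (i, j) is the correlation of the template whose top-left corner is
    placed at (row i, col j) of the region; values lie in [-1, 1].  Windows
    of the region with (numerically) zero variance correlate to 0.
    """
    region = np.asarray(frame_region, dtype=np.float64)
    template = np.asarray(template, dtype=np.float64)
    if template.std() == 0.0:
        raise DegenerateTemplateError("template has zero intensity variance")
    if region.shape[0] < template.shape[0] or region.shape[1] < template.shape[1]:
        raise ValueError(
            f"region {region.shape} smaller than template {template.shape}"
        )
    surface = match_template(region, template, pad_input=False)
    return np.clip(np.nan_to_num(surface, nan=0.0), -1.0, 1.0)


def subpixel_peak(surface: np.ndarray, peak_ij: Tuple[int, int]) -> Tuple[float, float, str]:
    """Sub-pixel offset of a correlation peak by elliptical-paraboloid fit.

    Least-squares fit of ``z = a + b x + c y + d x^2 + e y^2`` (axis-aligned,
    no cross-term) over the 3x3 neighbourhood of the integer peak; the vertex
    ``(-b/2d, -c/2e)`` is the refined offset, clamped to (-1, 1) per axis.
    Returns ``(dx, dy, flag)`` with flag in {"ok", "border", "degenerate"}.
    For any surface that *is* such a paraboloid the vertex is recovered
    exactly: the five basis monomials are linearly independent on the grid.
    """
    i, j = int(peak_ij[0]), int(peak_ij[1])
    h, w = surface.shape
    if i <= 0 or j <= 0 or i >= h - 1 or j >= w - 1:
        return 0.0, 0.0, "border"
    z = np.asarray(surface[i - 1 : i + 2, j - 1 : j + 2], dtype=np.float64)
    # orthogonal on the 3x3 grid: solve each coefficient by projection
    gx = np.array([-1.0, 0.0, 1.0])
    xs = np.tile(gx, (3, 1))
    ys = xs.T
    b = float((z * xs).sum() / 6.0)
    c = float((z * ys).sum() / 6.0)
    # (a, d, e) from the normal equations of the [1, x^2, y^2] block:
    #   9a + 6d + 6e = S;  6a + 6d + 4e = Sxx;  6a + 4d + 6e = Syy
    s = z.sum()
    sxx = float((z * xs * xs).sum())
    syy = float((z * ys * ys).sum())
    A = np.array([[9.0, 6.0, 6.0], [6.0, 6.0, 4.0], [6.0, 4.0, 6.0]])
    _, d, e = np.linalg.solve(A, np.array([s, sxx, syy]))
    if not (d < 0 and e < 0):
        return 0.0, 0.0, "degenerate"
    dx = float(np.clip(-b / (2.0 * d), -0.999999, 0.999999))
    dy = float(np.clip(-c / (2.0 * e), -0.999999, 0.999999))
    return dx, dy, "ok"


def _best_match(region: np.ndarray, template: np.ndarray):
    """Integer + sub-pixel peak of the NCC surface.

    Returns ``(peak_value, (col, row) sub-pixel top-left within region, flag)``.
    """
    surface = ncc_match(region, template)
    i, j = np.unravel_index(int(np.argmax(surface)), surface.shape)
    dx, dy, flag = subpixel_peak(surface, (i, j))
    return float(surface[i, j]), (j + dx, i + dy), flag


# ---------------------------------------------------------------------------
# pattern recovery
# ---------------------------------------------------------------------------

def _clip_rect(x, y, w, h, width, height):
    x0 = max(0, x)
    y0 = max(0, y)
    x1 = min(width, x + w)
    y1 = min(height, y + h)
    return x0, y0, x1 - x0, y1 - y0


def pattern_variants(initial_frame, pattern: PipettePattern, at_xy=None) -> List[PipettePattern]:
    """Dilated/eroded rectangle variants of a pattern, cut from a frame.

    ``at_xy`` overrides the rectangle's top-left corner (used when the
    pattern was located in the initial frame at a shifted position); the
    anchor offset shifts with the margin so all variants share the same
    physical anchor point.
    """
    x, y, w, h = pattern.rect_xy_wh
    if at_xy is not None:
        x, y = int(round(at_xy[0])), int(round(at_xy[1]))
    H, W = initial_frame.intensity.shape
    ax, ay = pattern.anchor_offset_xy
    variants = []
    for m in RECOVERY_MARGINS:
        vx, vy, vw, vh = _clip_rect(x - m, y - m, w + 2 * m, h + 2 * m, W, H)
        if vw < 3 or vh < 3:
            continue
        variants.append(
            PipettePattern(
                template=initial_frame.intensity[vy : vy + vh, vx : vx + vw].copy(),
                source_frame=initial_frame.index,
                rect_xy_wh=(vx, vy, vw, vh),
                anchor_offset_xy=(ax + (x - vx), ay + (y - vy)),
                pattern_id=f"{pattern.pattern_id}{'+' if m >= 0 else ''}{m}" if m else pattern.pattern_id,
            )
        )
    return variants


def recover_pattern(
    initial_frame,
    pattern: PipettePattern,
    problem_frame,
    threshold: float = DEFAULT_METRIC_THRESHOLD,
    search_region=None,
):
    """Rebuild the template when the correlation collapsed on one frame.

    First the current pattern must still localize reliably in the interval's
    initial frame (correlation at least ``threshold``; when that frame is the
    pattern's own source frame the peak must also sit within 1 px of the cut
    position) — otherwise the pattern itself is broken and the interval
    cannot be recovered.  Then rectangle variants with margins of +-2 and
    +-4 px per side are cut from the initial frame, each is matched in the
    problem frame, and the best-correlating variant wins.

    Returns ``(best_pattern, PipetteDetection)``; the detection carries flag
    ``recovered`` when the best variant clears the threshold and ``failed``
    otherwise.
    """
    m0, pos0, _ = _best_match(initial_frame.intensity, pattern.template)
    x, y, _, _ = pattern.rect_xy_wh
    if m0 < threshold:
        raise UnrecoverablePatternError(
            f"pattern {pattern.pattern_id} no longer matches the initial frame "
            f"{initial_frame.index} (M_p={m0:.3f} < {threshold})"
        )
    if initial_frame.index == pattern.source_frame and (
        abs(pos0[0] - x) > 1.0 or abs(pos0[1] - y) > 1.0
    ):
        raise UnrecoverablePatternError(
            f"pattern {pattern.pattern_id} drifted in its own source frame: "
            f"matched at {pos0}, cut at {(x, y)}"
        )
    variants = pattern_variants(initial_frame, pattern, at_xy=pos0)
    region = problem_frame.intensity if search_region is None else search_region
    best = None
    for var in variants:
        if var.template.std() == 0.0:
            continue
        if region.shape[0] < var.template.shape[0] or region.shape[1] < var.template.shape[1]:
            continue
        m, tl, _ = _best_match(region, var.template)
        if best is None or m > best[0]:
            best = (m, tl, var)
    if best is None:
        raise UnrecoverablePatternError("no usable pattern variant could be built")
    m, tl, var = best
    ax, ay = var.anchor_offset_xy
    det = PipetteDetection(
        frame=problem_frame.index,
        anchor_xy=(tl[0] + ax, tl[1] + ay),
        metric=m,
        pattern_id=var.pattern_id,
        flag="recovered" if m >= threshold else "failed",
        top_left_xy=tl,
    )
    return var, det


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------

def _search_window(last_tl, tmpl_shape, frame_shape, inflate: float = 1.0):
    """Search region around the last matched top-left: template rectangle
    inflated by half the template size per side (times ``inflate``)."""
    th, tw = tmpl_shape
    H, W = frame_shape
    mx = int(round(tw / 2 * inflate))
    my = int(round(th / 2 * inflate))
    x0 = int(round(last_tl[0])) - mx
    y0 = int(round(last_tl[1])) - my
    x1 = int(round(last_tl[0])) + tw + mx
    y1 = int(round(last_tl[1])) + th + my
    x0, y0 = max(0, x0), max(0, y0)
    x1, y1 = min(W, x1), min(H, y1)
    return x0, y0, x1, y1


def track_pipette(
    source,
    interval: Sequence[int],
    pattern: PipettePattern,
    threshold: float = DEFAULT_METRIC_THRESHOLD,
    max_consecutive_failures: int = DEFAULT_MAX_CONSECUTIVE_FAILURES,
) -> PipetteTrack:
    """Track the pipette anchor across an interval of frames.

    Per frame the template is matched in a restricted region around the last
    confirmed position (the whole frame for the first one), refined to
    sub-pixel.  On a sub-threshold correlation the region is regrown by 50%
    and re-searched; if still low, pattern recovery rebuilds the template
    from the interval's initial frame.  After ``max_consecutive_failures``
    consecutive failed frames the track aborts with a report naming the
    first bad frame; the partial track is returned, not discarded.
    """
    frames = [int(i) for i in interval]
    if not frames:
        raise ValueError("empty interval")
    track = PipetteTrack()
    current = pattern
    initial_frame = source.get_frame(frames[0])
    last_tl = None
    consecutive = 0
    for idx in frames:
        frame = source.get_frame(idx)
        img = frame.intensity
        if last_tl is None:
            region_off = (0, 0)
            region = img
        else:
            x0, y0, x1, y1 = _search_window(last_tl, current.template.shape, img.shape)
            region_off = (x0, y0)
            region = img[y0:y1, x0:x1]
        det = None
        try:
            m, tl, flag = _best_match(region, current.template)
        except (ValueError, DegenerateTemplateError):
            m, tl, flag = -1.0, (np.nan, np.nan), "failed"
        if m < threshold and last_tl is not None:
            # refinement 1: grow the search region by 50%
            x0, y0, x1, y1 = _search_window(
                last_tl, current.template.shape, img.shape, inflate=1.5
            )
            region_off = (x0, y0)
            region = img[y0:y1, x0:x1]
            try:
                m2, tl2, flag2 = _best_match(region, current.template)
                if m2 > m:
                    m, tl, flag = m2, tl2, flag2
            except (ValueError, DegenerateTemplateError):
                pass
        if m >= threshold:
            ax, ay = current.anchor_offset_xy
            abs_tl = (region_off[0] + tl[0], region_off[1] + tl[1])
            det = PipetteDetection(
                frame=idx,
                anchor_xy=(abs_tl[0] + ax, abs_tl[1] + ay),
                metric=m,
                pattern_id=current.pattern_id,
                flag="ok",
                top_left_xy=abs_tl,
            )
        else:
            # refinement 2: rebuild the template (dilation/erosion recovery)
            try:
                var, rdet = recover_pattern(initial_frame, current, frame, threshold)
                if rdet.flag == "recovered":
                    det = rdet
                    current = var  # replacement used from this frame onward
            except UnrecoverablePatternError as exc:
                track.aborted = True
                track.abort_report = str(exc)
                break
        if det is None:
            track.failed_frames.append(idx)
            consecutive += 1
            track.detections.append(
                PipetteDetection(
                    frame=idx,
                    anchor_xy=(np.nan, np.nan),
                    metric=m,
                    pattern_id=current.pattern_id,
                    flag="failed",
                )
            )
            if consecutive >= max_consecutive_failures:
                track.aborted = True
                track.abort_report = (
                    f"pipette lost: {consecutive} consecutive frames below "
                    f"M_p={threshold} starting at frame "
                    f"{track.failed_frames[-consecutive]}"
                )
                break
        else:
            consecutive = 0
            track.detections.append(det)
            last_tl = det.top_left_xy
    return track
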