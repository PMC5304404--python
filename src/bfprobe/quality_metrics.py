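"""Frame-contrast metrics used to pre-screen recordings and gate tracking.

Two scalar courses summarise image quality over time:

* **SD2** — the population standard deviation of pixel intensities of each
  frame, normalized by the maximum over the processed course.  Defocus,
  probe separation or field changes lower the spread of intensities, so a
  dip below a threshold (0.95 by default) marks frames to treat with care.
* **rSD2** — the running standard deviation of SD2 over a centred window
  (40 frames by default), again normalized by its maximum.  It highlights
  intervals of *fluctuating* contrast (focus hunting), which perturb
  template matching more than a stable focus offset does.

Both metrics are advisory: the module flags frames, the pipeline and the
user decide what to exclude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .curve_analysis import running_sd

DEFAULT_RSD2_WINDOW = 40
DEFAULT_SD2_THRESHOLD = 0.95


@dataclass
class ContrastCourse:
    """SD2 / rSD2 over a processed frame range."""

    frames: np.ndarray  # frame indices the metrics refer to
    raw_sd: np.ndarray  # per-frame population SD before normalization
    sd2: np.ndarray
    rsd2: np.ndarray
    window: int = DEFAULT_RSD2_WINDOW
    sd2_threshold: float = DEFAULT_SD2_THRESHOLD
    degenerate: bool = False
    time_s: Optional[np.ndarray] = None

    def to_frame(self):
        """Tabular view (pandas) with columns frame, time_s, sd2, rsd2."""
        import pandas as pd

        return pd.DataFrame(
            {
                "frame": self.frames,
                "time_s": self.time_s if self.time_s is not None else np.nan,
                "sd2": self.sd2,
                "rsd2": self.rsd2,
            }
        )


def frame_sd(intensity: np.ndarray) -> float:
    """Population SD of all pixel intensities of one frame."""
    arr = np.asarray(intensity, dtype=np.float64)
    if arr.size == 0 or np.ptp(arr) == 0.0:  # exact zero for constant frames
        return 0.0
    return float(np.std(arr))


def compute_sd2(source, frames: Sequence[int]):
    """Per-frame raw SD and course-normalized SD2.

    Returns ``(raw, sd2, degenerate)``.  ``degenerate`` is set when every
    frame is constant (max raw SD is zero), in which case sd2 is all zeros
    rather than 0/0.
    """
    frames = np.asarray(list(frames), dtype=int)
    if frames.size == 0:
        raise ValueError("empty frame range for contrast computation")
    raw = np.array([frame_sd(source.get_frame(int(i)).intensity) for i in frames])
    peak = raw.max()
    if peak == 0.0:
        return raw, np.zeros_like(raw), True
    return raw, raw / peak, False


def compute_rsd2(sd2: np.ndarray, window: int = DEFAULT_RSD2_WINDOW):
    """Running SD of the SD2 course, normalized by its own maximum.

    The window is centred with truncation at the edges.  Returns
    ``(rsd2, degenerate)``; a constant sd2 course yields all zeros.
    """
    sd2 = np.asarray(sd2, dtype=np.float64)
    if window < 2:
        raise ValueError(f"running window must be >= 2, got {window}")
    if sd2.size < window:
        raise ValueError(
            f"course of {sd2.size} frames shorter than running window {window}"
        )
    rs = running_sd(sd2, window)
    peak = rs.max()
    if peak == 0.0:
        return np.zeros_like(rs), True
    return rs / peak, False


def compute_contrast(
    source,
    frames: Sequence[int],
    window: int = DEFAULT_RSD2_WINDOW,
    sd2_threshold: float = DEFAULT_SD2_THRESHOLD,
) -> ContrastCourse:
    """Convenience wrapper building a full :class:`ContrastCourse`."""
    frames = np.asarray(list(frames), dtype=int)
    raw, sd2, degen_sd = compute_sd2(source, frames)
    if frames.size >= window:
        rsd2, degen_rs = compute_rsd2(sd2, window)
    else:  # course shorter than the window: report zeros, flag degenerate
        rsd2, degen_rs = np.zeros_like(sd2), True
    time_s = frames / source.fps if getattr(source, "fps", None) else None
    return ContrastCourse(
        frames=frames,
        raw_sd=raw,
        sd2=sd2,
        rsd2=rsd2,
        window=window,
        sd2_threshold=sd2_threshold,
        degenerate=degen_sd or degen_rs,
        time_s=time_s,
    )


def flag_low_contrast(course: ContrastCourse) -> List[int]:
    """Frame indices whose SD2 fell below the warning threshold, sorted."""
    below = course.sd2 < course.sd2_threshold
    return sorted(int(f) for f in course.frames[below])
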