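"""Post-hoc analysis of tracked courses: fits, plateaus, running-SD noise.

Force-spectroscopy time courses are usually summarised by a handful of
quantities: the loading rate (slope of force vs time), the relaxation time
of the probe after a step (exponential decay constant), and the mean force
over intervals of static equilibrium (plateaus).  The running standard
deviation over plateau intervals doubles as the empirical uncertainty of
the deformation (eps_Delta) and force (eps_F = k * eps_Delta) readouts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

DEFAULT_WINDOW = 40


@dataclass
class FitResult:
    model: str  # "line" | "exponential"
    params: Dict[str, float]
    rss: float
    frame_range: Tuple[int, int]
    ok: bool = True
    message: str = ""


@dataclass
class Plateau:
    first_frame: int
    last_frame: int
    mean_value: float
    sd_value: float

    @property
    def n_frames(self) -> int:
        return self.last_frame - self.first_frame + 1


# ---------------------------------------------------------------------------
# running statistics
# ---------------------------------------------------------------------------

def _window_bounds(n: int, window: int) -> Tuple[np.ndarray, np.ndarray]:
    """Centred-window bounds [lo, hi) per index, truncated at the edges.

    For window w the nominal window at index i is
    ``i - (w-1)//2 .. i + w//2`` inclusive (even windows carry the extra
    sample on the trailing side).
    """
    idx = np.arange(n)
    lo = np.clip(idx - (window - 1) // 2, 0, n)
    hi = np.clip(idx + window // 2 + 1, 0, n)
    return lo, hi


def running_sd(series: np.ndarray, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Centred running population SD with edge truncation.

    Used both for the rSD2 contrast metric and for the empirical force /
    deformation uncertainty on plateau intervals.
    """
    y = np.asarray(series, dtype=np.float64)
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    n = y.size
    y = y - y.mean()  # centring avoids catastrophic cancellation in E[y^2]-E[y]^2
    lo, hi = _window_bounds(n, window)
    c1 = np.concatenate(([0.0], np.cumsum(y)))
    c2 = np.concatenate(([0.0], np.cumsum(y * y)))
    cnt = (hi - lo).astype(np.float64)
    s1 = c1[hi] - c1[lo]
    s2 = c2[hi] - c2[lo]
    var = s2 / cnt - (s1 / cnt) ** 2
    return np.sqrt(np.clip(var, 0.0, None))


def _running_slope(t: np.ndarray, y: np.ndarray, window: int) -> np.ndarray:
    """Per-index least-squares slope of y vs t over the centred window."""
    n = y.size
    lo, hi = _window_bounds(n, window)
    cnt = (hi - lo).astype(np.float64)

    def wsum(a):
        c = np.concatenate(([0.0], np.cumsum(a)))
        return c[hi] - c[lo]

    st, sy, stt, sty = wsum(t), wsum(y), wsum(t * t), wsum(t * y)
    var_t = stt / cnt - (st / cnt) ** 2
    cov_ty = sty / cnt - (st / cnt) * (sy / cnt)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(var_t > 0, cov_ty / np.where(var_t > 0, var_t, 1.0), 0.0)
    return slope


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

def fit_line(t: np.ndarray, y: np.ndarray, frame_range: Optional[Tuple[int, int]] = None) -> FitResult:
    """Least-squares straight line; slope is the loading rate when y is force
    in pN and t in seconds."""
    t = np.asarray(t, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if t.size != y.size:
        raise ValueError("t and y must have equal length")
    if t.size < 2:
        raise ValueError("a line fit needs at least 2 points")
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    rng = frame_range if frame_range is not None else (0, t.size - 1)
    return FitResult(
        model="line",
        params={"slope": float(slope), "intercept": float(intercept)},
        rss=float(resid @ resid),
        frame_range=rng,
    )


def _exp_model(t, c, a, tau):
    return c + a * np.exp(-t / tau)


def fit_exponential(t: np.ndarray, y: np.ndarray, frame_range: Optional[Tuple[int, int]] = None) -> FitResult:
    """Fit ``y(t) = c + a exp(-t/tau)`` by nonlinear least squares.

    The offset c is explicit because force plateaus rarely relax to zero.
    The initial guess log-linearizes ``y - c0`` with c0 taken from the tail
    of the series; non-convergence or a degenerate (constant) series comes
    back as ``ok=False``, never as an exception.
    """
    from scipy.optimize import curve_fit

    t = np.asarray(t, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if t.size != y.size:
        raise ValueError("t and y must have equal length")
    if t.size < 4:
        raise ValueError("an exponential fit needs at least 4 points")
    rng = frame_range if frame_range is not None else (0, t.size - 1)
    if np.ptp(y) == 0.0:
        return FitResult(
            model="exponential",
            params={"offset": float(y[0]), "amplitude": 0.0, "tau": np.nan},
            rss=0.0,
            frame_range=rng,
            ok=False,
            message="degenerate: constant series",
        )
    # initial guess from log-linearization of the tail-anchored residual
    tail = y[max(1, int(0.9 * y.size)):]
    c0 = float(np.mean(tail))
    a0 = float(y[0] - c0)
    span = float(t[-1] - t[0]) or 1.0
    tau0 = span / 3.0
    if a0 != 0.0:
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (y - c0) / a0
            mask = z > 1e-12
            if mask.sum() >= 2:
                s, _ = np.polyfit(t[mask], np.log(z[mask]), 1)
                if s < 0:
                    tau0 = -1.0 / s
    try:
        popt, _ = curve_fit(
            _exp_model,
            t,
            y,
            p0=(c0, a0, tau0),
            bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        return FitResult(
            model="exponential",
            params={"offset": np.nan, "amplitude": np.nan, "tau": np.nan},
            rss=np.inf,
            frame_range=rng,
            ok=False,
            message=f"fit failed: {exc}",
        )
    resid = y - _exp_model(t, *popt)
    return FitResult(
        model="exponential",
        params={"offset": float(popt[0]), "amplitude": float(popt[1]), "tau": float(popt[2])},
        rss=float(resid @ resid),
        frame_range=rng,
    )


# ---------------------------------------------------------------------------
# plateau detection
# ---------------------------------------------------------------------------

def detect_plateaus(
    series: np.ndarray,
    window: int = DEFAULT_WINDOW,
    slope_tol: Optional[float] = None,
    sd_tol: Optional[float] = None,
    min_length: Optional[int] = None,
    dt: float = 1.0,
) -> List[Plateau]:
    """Mark intervals of static equilibrium in a force / deformation course.

    A frame belongs to a plateau when, over its centred window,
    ``|fitted slope| * window_duration <= slope_tol`` (total drift across
    the window stays within tolerance) **and** the window SD is at most
    ``sd_tol``.  Adjacent marked frames merge, runs separated by a gap
    shorter than half a window merge too (the per-window slope statistic
    fluctuates at a sizeable fraction of the noise floor, so isolated
    excursions would otherwise fragment genuine plateaus), and runs
    shorter than ``min_length`` are discarded.  Default tolerances derive
    from the series' own noise floor: the median running SD, times 1.0
    for the drift bound and 1.5 for the SD bound.

    Parameters
    ----------
    dt:
        seconds per frame (1/fps); slopes are per second.
    """
    y = np.asarray(series, dtype=np.float64)
    if y.size < window:
        raise ValueError(f"series of {y.size} frames shorter than window {window}")
    if min_length is None:
        min_length = window
    rsd = running_sd(y, window)
    noise = float(np.median(rsd))
    if slope_tol is None:
        slope_tol = 1.0 * noise
    if sd_tol is None:
        sd_tol = 1.5 * noise
    t = np.arange(y.size) * dt
    slope = _running_slope(t, y, window)
    lo, hi = _window_bounds(y.size, window)
    duration = (hi - lo) * dt
    marked = (np.abs(slope) * duration <= slope_tol) & (rsd <= sd_tol)
    # raw runs of marked frames
    edges = np.flatnonzero(np.diff(np.r_[0, marked.astype(int), 0]))
    runs = [(int(edges[k]), int(edges[k + 1] - 1)) for k in range(0, edges.size, 2)]
    # bridge short unmarked gaps (isolated statistical excursions)
    merged: List[List[int]] = []
    for start, stop in runs:
        if merged and start - merged[-1][1] - 1 < window // 2:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    plateaus: List[Plateau] = []
    for start, stop in merged:
        if stop - start + 1 >= min_length:
            seg = y[start : stop + 1]
            plateaus.append(
                Plateau(
                    first_frame=start,
                    last_frame=stop,
                    mean_value=float(seg.mean()),
                    sd_value=float(seg.std()),
                )
            )
    return plateaus


def plateau_uncertainty(series: np.ndarray, plateaus: List[Plateau], window: int = DEFAULT_WINDOW) -> float:
    """Empirical readout uncertainty: mean running SD over plateau frames.

    Applied to the deformation course it estimates eps_Delta; multiplied by
    the probe stiffness it gives the force uncertainty eps_F.  Only frames
    whose full window fits inside the plateau contribute, so the estimate
    never mixes in the manipulation ramps flanking the equilibrium; that is
    what keeps it nearly independent of the window size.
    """
    if not plateaus:
        return float("nan")
    rsd = running_sd(np.asarray(series, dtype=np.float64), window)
    half = window // 2
    chunks = []
    for p in plateaus:
        lo, hi = p.first_frame + half, p.last_frame + 1 - half
        if hi <= lo:  # plateau shorter than the window: use it whole
            lo, hi = p.first_frame, p.last_frame + 1
        chunks.append(rsd[lo:hi])
    vals = np.concatenate(chunks)
    return float(vals.mean())
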