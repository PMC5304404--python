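"""Multi-interval analysis orchestration.

Real recordings rarely track end to end: focus falters, the probe
separates, the field gets littered.  The pipeline therefore operates on a
*chain* of disjoint frame intervals, each binding a pipette pattern, a
bead seed (explicit, or continued from the previous interval) and an
optional zero-load reference frame.  Intervals whose reference frame lives
in another interval of the chain inherit that interval's reference
distance, so their forces share one calibration; intervals with a locally
cut pattern and no usable reference can instead be shifted by a manual
force offset to align with their neighbour.

Per interval the frames are read once into a buffer and handed to both
trackers; contrast metrics are normalized over the union of all processed
intervals so chained analyses stay mutually comparable.  Tracking failures
are logged and reported, never raised: a failed analysis returns a partial
result with an abort report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import quality_metrics
from .bead_tracker import BeadDetection, BeadSpec, BeadTrack, track_bead
from .curve_analysis import running_sd
from .pipette_tracker import (
    PipetteDetection,
    PipettePattern,
    PipetteTrack,
    track_pipette,
)
from .probe_model import (
    GENERIC_GEOMETRY,
    ForceCourse,
    ProbeGeometry,
    compute_force,
    compute_stiffness,
)
from .video_io import FrameBuffer, VideoSource

logger = logging.getLogger("bfprobe")

SESSION_VERSION = 1

#: number of significant digits in CSV exports; enough for a lossless
#: round-trip of float32-scale measurement values
CSV_FLOAT_FORMAT = "%.9g"


class ChainValidationError(ValueError):
    """One or more problems with an interval chain; lists all of them."""

    def __init__(self, problems: List[str]):
        self.problems = list(problems)
        super().__init__("invalid interval chain:\n  - " + "\n  - ".join(problems))


class SessionError(ValueError):
    """Session file unreadable or from an incompatible version."""


@dataclass
class Interval:
    first_frame: int
    last_frame: int
    pattern_id: str
    bead_seed: Union[Tuple[float, float], str]  # (x, y) or "continue"
    t0_frame: Optional[int] = None
    offset_pN: float = 0.0

    def __post_init__(self) -> None:
        if self.first_frame > self.last_frame:
            raise ValueError(
                f"interval ({self.first_frame}, {self.last_frame}) has first > last"
            )

    @property
    def frames(self) -> range:
        return range(self.first_frame, self.last_frame + 1)

    def to_dict(self) -> dict:
        seed = self.bead_seed if isinstance(self.bead_seed, str) else list(self.bead_seed)
        return {
            "first_frame": self.first_frame,
            "last_frame": self.last_frame,
            "pattern_id": self.pattern_id,
            "bead_seed": seed,
            "t0_frame": self.t0_frame,
            "offset_pN": self.offset_pN,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Interval":
        seed = d["bead_seed"]
        if not isinstance(seed, str):
            seed = tuple(seed)
        return cls(
            first_frame=int(d["first_frame"]),
            last_frame=int(d["last_frame"]),
            pattern_id=d["pattern_id"],
            bead_seed=seed,
            t0_frame=d.get("t0_frame"),
            offset_pN=float(d.get("offset_pN", 0.0)),
        )


@dataclass
class IntervalResult:
    interval: Interval
    bead_track: BeadTrack
    pipette_track: PipetteTrack
    contrast: "quality_metrics.ContrastCourse"
    force: Optional[ForceCourse] = None


@dataclass
class AnalysisResult:
    intervals: List[IntervalResult] = field(default_factory=list)
    warnings: List[Tuple[int, str]] = field(default_factory=list)  # (frame, kind)
    report: Dict[str, object] = field(default_factory=dict)
    aborted: bool = False

    def to_frame(self):
        """One combined table over all intervals, sorted by frame."""
        import pandas as pd

        rows = []
        for k, ir in enumerate(self.intervals):
            bd = {d.frame: d for d in ir.bead_track.detections}
            pd_ = {d.frame: d for d in ir.pipette_track.detections}
            con = {int(f): (s, r) for f, s, r in zip(ir.contrast.frames, ir.contrast.sd2, ir.contrast.rsd2)}
            fc = ir.force
            fmap = (
                {int(f): i for i, f in enumerate(fc.frames)} if fc is not None else {}
            )
            for f in ir.interval.frames:
                b = bd.get(f)
                p = pd_.get(f)
                s, r = con.get(f, (np.nan, np.nan))
                row = {
                    "frame": f,
                    "time_s": (fc.time_s[fmap[f]] if fc is not None and fc.time_s is not None and f in fmap else np.nan),
                    "interval": k,
                    "bead_x_px": b.centre_xy[0] if b else np.nan,
                    "bead_y_px": b.centre_xy[1] if b else np.nan,
                    "bead_r_px": b.radius_px if b else np.nan,
                    "M_b": b.metric if b else np.nan,
                    "bead_flag": b.flag if b else "missing",
                    "pip_x_px": p.anchor_xy[0] if p else np.nan,
                    "pip_y_px": p.anchor_xy[1] if p else np.nan,
                    "M_p": p.metric if p else np.nan,
                    "pip_flag": p.flag if p else "missing",
                    "pattern_id": p.pattern_id if p else "",
                    "sd2": s,
                    "rsd2": r,
                    "x_um": fc.x_um[fmap[f]] if fc is not None and f in fmap else np.nan,
                    "dx_um": fc.dx_um[fmap[f]] if fc is not None and f in fmap else np.nan,
                    "force_pN": fc.F_pN[fmap[f]] if fc is not None and f in fmap else np.nan,
                    "calibrated": int(fc.calibrated) if fc is not None else 0,
                    "nonlinear_flag": (
                        int(fc.nonlinear_flags[fmap[f]]) if fc is not None and f in fmap else 0
                    ),
                }
                rows.append(row)
        return pd.DataFrame(rows).sort_values("frame", kind="stable").reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# chain validation
# ---------------------------------------------------------------------------

def validate_chain(
    intervals: Sequence[Interval],
    source,
    patterns: Dict[str, PipettePattern],
):
    """Normalize and verify an interval chain.

    Returns ``(chain, advisories)`` where ``chain`` is sorted by first
    frame and ``advisories`` are non-fatal notes (e.g. an interval whose
    reference frame lies outside every interval, which will come out
    uncalibrated).  Hard violations — overlapping ranges, frames outside
    the video, unknown pattern ids, a first interval without an explicit
    bead seed — raise :class:`ChainValidationError` enumerating *all*
    problems at once.
    """
    problems: List[str] = []
    advisories: List[str] = []
    chain = sorted(intervals, key=lambda iv: iv.first_frame)
    if not chain:
        problems.append("empty interval chain")
        raise ChainValidationError(problems)
    n_frames = getattr(source, "n_frames", None)
    covered = set()
    for k, iv in enumerate(chain):
        if n_frames is not None and (iv.first_frame < 0 or iv.last_frame >= n_frames):
            problems.append(
                f"interval {k} ({iv.first_frame}-{iv.last_frame}) outside video "
                f"with {n_frames} frames"
            )
        if k > 0 and iv.first_frame <= chain[k - 1].last_frame:
            problems.append(
                f"interval {k} ({iv.first_frame}-{iv.last_frame}) overlaps "
                f"interval {k - 1} ({chain[k-1].first_frame}-{chain[k-1].last_frame})"
            )
        if iv.pattern_id not in patterns:
            problems.append(f"interval {k}: unknown pattern id {iv.pattern_id!r}")
        if isinstance(iv.bead_seed, str):
            if iv.bead_seed != "continue":
                problems.append(
                    f"interval {k}: bead seed must be a position or 'continue', "
                    f"got {iv.bead_seed!r}"
                )
            elif k == 0:
                problems.append(
                    "interval 0: bead seed 'continue' has no predecessor to continue from"
                )
        covered.update(iv.frames)
    for k, iv in enumerate(chain):
        if iv.t0_frame is not None and iv.t0_frame not in covered:
            advisories.append(
                f"interval {k}: reference frame t0={iv.t0_frame} lies in no "
                "tracked interval; the interval will be uncalibrated"
            )
    if problems:
        raise ChainValidationError(problems)
    return chain, advisories


# ---------------------------------------------------------------------------
# analysis
# ---------------------------------------------------------------------------

def run_analysis(
    source: VideoSource,
    intervals: Sequence[Interval],
    bead_spec: BeadSpec,
    patterns: Dict[str, PipettePattern],
    geometry: Optional[ProbeGeometry] = None,
    pipette_threshold: float = 0.95,
    contrast_window: int = quality_metrics.DEFAULT_RSD2_WINDOW,
    sd2_threshold: float = quality_metrics.DEFAULT_SD2_THRESHOLD,
    projected: bool = False,
) -> AnalysisResult:
    """Run the full tracking and force computation over an interval chain.

    Per interval: contrast metrics, pipette track, bead track, deformation
    against the interval's effective reference frame (own t0, a frame
    tracked in another interval, or first-frame fallback), then force —
    calibrated when geometry *and* a proper reference are available,
    generic (order-of-magnitude) otherwise.  ``offset_pN`` of each interval
    is added to its force course for manual inter-interval alignment.
    Tracking aborts yield a partial result with a report, never an
    exception.
    """
    from dataclasses import replace as _replace

    chain, advisories = validate_chain(intervals, source, patterns)
    result = AnalysisResult()
    result.report["advisories"] = advisories

    # --- track every interval (frames read once, shared by both trackers)
    raw_sd_all: List[np.ndarray] = []
    for k, iv in enumerate(chain):
        frames = list(iv.frames)
        buf = FrameBuffer(source, frames)
        raw = np.array(
            [quality_metrics.frame_sd(buf.get_frame(i).intensity) for i in frames]
        )
        raw_sd_all.append(raw)
        ptrack = track_pipette(
            buf, frames, patterns[iv.pattern_id], threshold=pipette_threshold,
            max_consecutive_failures=bead_spec.max_consecutive_failures,
        )
        if isinstance(iv.bead_seed, str):  # "continue"
            prev = result.intervals[k - 1].bead_track.last_confirmed_centre
            if prev is None:
                result.aborted = True
                result.report[f"interval_{k}"] = (
                    "cannot continue bead seed: previous interval has no confirmed centre"
                )
                break
            seed = prev
        else:
            seed = tuple(iv.bead_seed)
        btrack = track_bead(buf, frames, _replace(bead_spec, seed_xy=seed))
        contrast = quality_metrics.ContrastCourse(
            frames=np.asarray(frames, dtype=int),
            raw_sd=raw,
            sd2=np.zeros_like(raw),  # filled after global normalization
            rsd2=np.zeros_like(raw),
            window=contrast_window,
            sd2_threshold=sd2_threshold,
        )
        result.intervals.append(IntervalResult(iv, btrack, ptrack, contrast))
        if btrack.aborted or ptrack.aborted:
            result.aborted = True

    # --- contrast normalization over the union of processed intervals
    gmax = max((r.max() for r in raw_sd_all if r.size), default=0.0)
    rsd_raw: List[np.ndarray] = []
    for ir, raw in zip(result.intervals, raw_sd_all):
        sd2 = raw / gmax if gmax > 0 else np.zeros_like(raw)
        ir.contrast.sd2 = sd2
        win = min(contrast_window, max(2, sd2.size))
        rsd_raw.append(running_sd(sd2, win) if sd2.size >= 2 else np.zeros_like(sd2))
    rmax = max((r.max() for r in rsd_raw if r.size), default=0.0)
    for ir, rs in zip(result.intervals, rsd_raw):
        ir.contrast.rsd2 = rs / rmax if rmax > 0 else rs
        if source.fps:
            ir.contrast.time_s = ir.contrast.frames / source.fps

    # --- deformation and force
    x_global: Dict[int, float] = {}
    aligned: List[Tuple[IntervalResult, np.ndarray, np.ndarray]] = []
    for ir in result.intervals:
        bf, pf = ir.bead_track.frames, ir.pipette_track.frames
        common = np.intersect1d(bf, pf)
        aligned.append((ir, common, common))
        if common.size == 0:
            continue
        bsel = np.isin(bf, common)
        psel = np.isin(pf, common)
        bead_xy = ir.bead_track.positions[bsel]
        anchor_xy = ir.pipette_track.positions[psel]
        delta = anchor_xy - bead_xy
        x_px = np.abs(delta[:, 0]) if projected else np.hypot(delta[:, 0], delta[:, 1])
        scale = source.pixel_scale if source.pixel_scale else 1.0
        x_um = x_px * scale
        for f, x in zip(common, x_um):
            x_global[int(f)] = float(x)

    k_value = compute_stiffness(geometry) if geometry is not None else compute_stiffness(GENERIC_GEOMETRY)
    for ir, common, _ in aligned:
        if common.size == 0:
            continue
        x_um = np.array([x_global[int(f)] for f in common])
        t0 = ir.interval.t0_frame
        t0_ok = t0 is not None and int(t0) in x_global and np.isfinite(x_global[int(t0)])
        if t0_ok:
            x0 = x_global[int(t0)]
        else:
            finite = x_um[np.isfinite(x_um)]
            x0 = float(finite[0]) if finite.size else float("nan")
        dx = x_um - x0
        force, nonlinear = compute_force(dx, k_value)
        force = force + ir.interval.offset_pN
        calibrated = bool(t0_ok and geometry is not None and source.pixel_scale)
        time_s = common / source.fps if source.fps else None
        ir.force = ForceCourse(
            frames=common,
            x_um=x_um,
            x0_um=x0,
            dx_um=dx,
            k_pN_per_um=k_value,
            F_pN=force,
            calibrated=calibrated,
            nonlinear_flags=nonlinear,
            time_s=time_s,
        )

    # --- warnings: every flagged frame in any track or metric
    for k, ir in enumerate(result.intervals):
        for f in quality_metrics.flag_low_contrast(ir.contrast):
            result.warnings.append((f, "low_contrast"))
        for d in ir.bead_track.detections:
            if d.flag != "ok":
                result.warnings.append((d.frame, f"bead_{d.flag}"))
        for d in ir.pipette_track.detections:
            if d.flag != "ok":
                result.warnings.append((d.frame, f"pipette_{d.flag}"))
        if ir.force is not None:
            for f in ir.force.frames[ir.force.nonlinear_flags]:
                result.warnings.append((int(f), "nonlinear_regime"))
            if not ir.force.calibrated:
                result.report[f"interval_{k}_uncalibrated"] = True
        if ir.bead_track.aborted:
            result.report[f"interval_{k}_bead_abort"] = ir.bead_track.abort_report
        if ir.pipette_track.aborted:
            result.report[f"interval_{k}_pipette_abort"] = ir.pipette_track.abort_report
    result.warnings.sort()
    result.report["n_warnings"] = len(result.warnings)
    result.report["n_failed_bead_frames"] = sum(
        len(ir.bead_track.failed_frames) for ir in result.intervals
    )
    result.report["n_failed_pipette_frames"] = sum(
        len(ir.pipette_track.failed_frames) for ir in result.intervals
    )
    for f, kind in result.warnings:
        logger.warning("frame %d: %s", f, kind)
    return result


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------

def _det_to_dict(d) -> dict:
    out = dict(d.__dict__)
    for key, val in out.items():
        if isinstance(val, tuple):
            out[key] = list(val)
        elif isinstance(val, np.floating):
            out[key] = float(val)
        elif isinstance(val, np.integer):
            out[key] = int(val)
    return out


def save_session(result: AnalysisResult, chain, config: dict, path, patterns=None) -> None:
    """Write the whole analysis state to one JSON document.

    The video itself is referenced by path inside ``config``, never
    embedded; re-tracking on another machine needs the recording present.
    """
    doc = {
        "version": SESSION_VERSION,
        "config": config,
        "chain": [iv.to_dict() for iv in chain],
        "patterns": {pid: p.to_dict() for pid, p in (patterns or {}).items()},
        "warnings": [[int(f), kind] for f, kind in result.warnings],
        "report": result.report,
        "aborted": result.aborted,
        "intervals": [],
    }
    for ir in result.intervals:
        entry = {
            "interval": ir.interval.to_dict(),
            "bead": {
                "detections": [_det_to_dict(d) for d in ir.bead_track.detections],
                "failed_frames": ir.bead_track.failed_frames,
                "aborted": ir.bead_track.aborted,
                "abort_report": ir.bead_track.abort_report,
            },
            "pipette": {
                "detections": [_det_to_dict(d) for d in ir.pipette_track.detections],
                "failed_frames": ir.pipette_track.failed_frames,
                "aborted": ir.pipette_track.aborted,
                "abort_report": ir.pipette_track.abort_report,
            },
            "contrast": {
                "frames": ir.contrast.frames.tolist(),
                "raw_sd": ir.contrast.raw_sd.tolist(),
                "sd2": ir.contrast.sd2.tolist(),
                "rsd2": ir.contrast.rsd2.tolist(),
                "window": ir.contrast.window,
                "sd2_threshold": ir.contrast.sd2_threshold,
                "time_s": None if ir.contrast.time_s is None else ir.contrast.time_s.tolist(),
            },
            "force": None,
        }
        if ir.force is not None:
            fc = ir.force
            entry["force"] = {
                "frames": fc.frames.tolist(),
                "x_um": fc.x_um.tolist(),
                "x0_um": fc.x0_um,
                "dx_um": fc.dx_um.tolist(),
                "k_pN_per_um": fc.k_pN_per_um,
                "F_pN": fc.F_pN.tolist(),
                "calibrated": fc.calibrated,
                "nonlinear_flags": fc.nonlinear_flags.astype(int).tolist(),
                "time_s": None if fc.time_s is None else fc.time_s.tolist(),
            }
        doc["intervals"].append(entry)
    Path(path).write_text(json.dumps(doc))


def load_session(path):
    """Read a session back; returns ``(result, chain, config, patterns)``.

    The stored results are fully usable without the video; re-tracking
    requires the recording referenced in the config to exist again.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise SessionError(f"cannot read session {path}: {exc}") from None
    version = doc.get("version")
    if version != SESSION_VERSION:
        raise SessionError(
            f"session {path} has version {version}, this build reads version "
            f"{SESSION_VERSION}"
        )
    chain = [Interval.from_dict(d) for d in doc["chain"]]
    patterns = {
        pid: PipettePattern.from_dict(d) for pid, d in doc.get("patterns", {}).items()
    }
    result = AnalysisResult(
        warnings=[(int(f), kind) for f, kind in doc["warnings"]],
        report=doc["report"],
        aborted=doc["aborted"],
    )
    for entry in doc["intervals"]:
        iv = Interval.from_dict(entry["interval"])
        bt = BeadTrack(
            detections=[
                BeadDetection(
                    frame=d["frame"],
                    centre_xy=tuple(d["centre_xy"]),
                    radius_px=d["radius_px"],
                    metric=d["metric"],
                    raw_metric=d["raw_metric"],
                    distance_factor=d["distance_factor"],
                    flag=d["flag"],
                )
                for d in entry["bead"]["detections"]
            ],
            failed_frames=entry["bead"]["failed_frames"],
            aborted=entry["bead"]["aborted"],
            abort_report=entry["bead"]["abort_report"],
        )
        pt = PipetteTrack(
            detections=[
                PipetteDetection(
                    frame=d["frame"],
                    anchor_xy=tuple(d["anchor_xy"]),
                    metric=d["metric"],
                    pattern_id=d["pattern_id"],
                    flag=d["flag"],
                    top_left_xy=tuple(d["top_left_xy"]),
                )
                for d in entry["pipette"]["detections"]
            ],
            failed_frames=entry["pipette"]["failed_frames"],
            aborted=entry["pipette"]["aborted"],
            abort_report=entry["pipette"]["abort_report"],
        )
        cd = entry["contrast"]
        contrast = quality_metrics.ContrastCourse(
            frames=np.asarray(cd["frames"], dtype=int),
            raw_sd=np.asarray(cd["raw_sd"]),
            sd2=np.asarray(cd["sd2"]),
            rsd2=np.asarray(cd["rsd2"]),
            window=cd["window"],
            sd2_threshold=cd["sd2_threshold"],
            time_s=None if cd["time_s"] is None else np.asarray(cd["time_s"]),
        )
        force = None
        if entry["force"] is not None:
            fd = entry["force"]
            force = ForceCourse(
                frames=np.asarray(fd["frames"], dtype=int),
                x_um=np.asarray(fd["x_um"]),
                x0_um=fd["x0_um"],
                dx_um=np.asarray(fd["dx_um"]),
                k_pN_per_um=fd["k_pN_per_um"],
                F_pN=np.asarray(fd["F_pN"]),
                calibrated=fd["calibrated"],
                nonlinear_flags=np.asarray(fd["nonlinear_flags"], dtype=bool),
                time_s=None if fd["time_s"] is None else np.asarray(fd["time_s"]),
            )
        result.intervals.append(IntervalResult(iv, bt, pt, contrast, force))
    return result, chain, doc.get("config", {}), patterns
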