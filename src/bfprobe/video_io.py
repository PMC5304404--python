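"""Uniform, metadata-aware frame access over TIFF stacks and video containers.

Biomembrane-force-probe recordings arrive either as multi-page TIFF stacks
(the reliable baseline: grayscale or RGB, 8/16-bit) or as consumer video
containers (AVI/MP4/MOV).  This module hides the difference behind a single
:class:`VideoSource` with lazy frame access and explicit metadata (framerate,
pixel scale), because downstream force computation needs real time stamps and
physical units.

Conventions used throughout the package:

* coordinates are 0-based ``(x, y) = (column, row)``, x growing rightward and
  y downward; sub-pixel positions are real-valued in this frame;
* intensities are floats in ``[0, 1]``, normalized by the container's nominal
  maximum (255 for 8-bit, 65535 for 16-bit), **never** per-frame min/max —
  per-frame normalization would silently flatten the SD2 contrast metric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

# ITU-R BT.709 luminance weights, applied when colour input is encountered.
LUMA_WEIGHTS = (0.2126, 0.7152, 0.0722)

_TIFF_SUFFIXES = {".tif", ".tiff"}


class VideoIOError(IOError):
    """Unreadable or malformed recording."""


class VideoFormatError(VideoIOError):
    """File opened but holds no usable frames."""


class MetadataError(ValueError):
    """A time- or scale-dependent operation was attempted without metadata."""


@dataclass
class Frame:
    """One grayscale frame, intensity scaled to [0, 1]."""

    index: int
    time_s: Optional[float]
    intensity: np.ndarray


@dataclass
class VideoSource:
    """Handle to an opened recording plus its metadata.

    ``fps`` and ``pixel_scale`` may be ``None`` until provided; operations
    that need them raise :class:`MetadataError` with an explicit message
    instead of guessing.
    """

    path: Path
    n_frames: int
    height: int
    width: int
    fps: Optional[float] = None
    pixel_scale: Optional[float] = None
    bit_depth: int = 8
    _pages: object = field(default=None, repr=False)
    _frames: Optional[np.ndarray] = field(default=None, repr=False)
    _nominal_max: float = field(default=255.0, repr=False)

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise VideoFormatError(f"{self.path}: recording holds no frames")
        if self.fps is not None and not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.pixel_scale is not None and not self.pixel_scale > 0:
            raise ValueError(f"pixel_scale must be positive, got {self.pixel_scale}")

    # -- metadata ----------------------------------------------------------

    def time_of(self, index: int) -> float:
        if self.fps is None:
            raise MetadataError(
                f"{self.path}: framerate unknown; pass fps_override to open_video "
                "or set source.fps before using time-dependent operations"
            )
        return index / self.fps

    def require_pixel_scale(self) -> float:
        if self.pixel_scale is None:
            raise MetadataError(
                f"{self.path}: pixel scale (um/px) unknown; calibrate it from an "
                "object of known length (calibrate_scale) and set source.pixel_scale"
            )
        return self.pixel_scale

    # -- frame access ------------------------------------------------------

    def get_frame(self, index: int) -> Frame:
        return get_frame(self, index)

    def iter_frames(self, indices):
        for i in indices:
            yield self.get_frame(i)


def _to_grayscale_unit(raw: np.ndarray, nominal_max: float) -> np.ndarray:
    """Collapse colour to luminance and rescale to [0, 1] by the nominal max."""
    arr = np.asarray(raw)
    if arr.ndim == 3:
        if arr.shape[-1] == 4:  # drop alpha
            arr = arr[..., :3]
        if arr.shape[-1] == 3:
            arr = arr.astype(np.float64) @ np.asarray(LUMA_WEIGHTS)
        else:
            raise VideoFormatError(f"unsupported frame shape {arr.shape}")
    out = arr.astype(np.float64) / nominal_max
    return np.clip(out, 0.0, 1.0)


def _nominal_max_for(dtype: np.dtype) -> tuple[float, int]:
    dtype = np.dtype(dtype)
    if dtype.kind == "u" or dtype.kind == "i":
        bits = dtype.itemsize * 8
        return float(2**bits - 1), bits
    if dtype.kind == "f":
        return 1.0, 32
    raise VideoFormatError(f"unsupported sample type {dtype}")


def open_video(path, fps_override: Optional[float] = None) -> VideoSource:
    """Open a TIFF stack or video container and populate metadata.

    TIFF stacks written by this package carry a JSON ImageDescription with
    ``fps`` and ``pixel_scale``; third-party TIFFs often populate neither, in
    which case ``fps`` stays unset unless ``fps_override`` is given.  A source
    with unset fps is still fully usable for tracking — only time-dependent
    quantities refuse to compute.
    """
    path = Path(path)
    if not path.exists():
        raise VideoIOError(f"cannot open recording: {path} does not exist")
    if path.suffix.lower() in _TIFF_SUFFIXES:
        src = _open_tiff(path)
    else:
        src = _open_container(path)
    if fps_override is not None:
        if not fps_override > 0:
            raise ValueError(f"fps_override must be positive, got {fps_override}")
        src.fps = float(fps_override)
    return src


def _open_tiff(path: Path) -> VideoSource:
    import tifffile

    try:
        tif = tifffile.TiffFile(path)
    except Exception as exc:  # tifffile raises assorted types on corruption
        raise VideoIOError(f"cannot read TIFF {path}: {exc}") from None
    pages = tif.pages
    if len(pages) == 0:
        raise VideoFormatError(f"{path}: TIFF holds no pages")
    first = pages[0].asarray()
    nominal_max, bits = _nominal_max_for(first.dtype)
    fps = None
    pixel_scale = None
    desc = pages[0].description
    if desc:
        try:
            meta = json.loads(desc)
            fps = meta.get("fps")
            pixel_scale = meta.get("pixel_scale")
        except (json.JSONDecodeError, AttributeError):
            pass
    h, w = first.shape[:2]
    return VideoSource(
        path=path,
        n_frames=len(pages),
        height=int(h),
        width=int(w),
        fps=fps,
        pixel_scale=pixel_scale,
        bit_depth=bits,
        _pages=tif,
        _nominal_max=nominal_max,
    )


def _open_container(path: Path) -> VideoSource:
    try:
        import imageio.v3 as iio

        frames = np.asarray(iio.imread(path, index=None))
        meta = iio.immeta(path)
    except VideoIOError:
        raise
    except Exception as exc:
        raise VideoIOError(
            f"cannot decode {path}: {exc} (no backend for this container?)"
        ) from None
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim == 4 or frames.ndim == 3 and frames.shape[-1] in (3, 4):
        pass
    if frames.shape[0] == 0:
        raise VideoFormatError(f"{path}: container holds no frames")
    fps = meta.get("fps")
    nominal_max, bits = _nominal_max_for(frames.dtype)
    h, w = frames.shape[1:3]
    return VideoSource(
        path=path,
        n_frames=int(frames.shape[0]),
        height=int(h),
        width=int(w),
        fps=float(fps) if fps else None,
        bit_depth=bits,
        _frames=frames,
        _nominal_max=nominal_max,
    )


def get_frame(source: VideoSource, index: int) -> Frame:
    """Read one frame as grayscale [0, 1] intensity.  Pure: re-reads agree."""
    if not 0 <= index < source.n_frames:
        raise IndexError(
            f"frame {index} out of range [0, {source.n_frames}) for {source.path}"
        )
    if source._frames is not None:
        raw = source._frames[index]
    else:
        raw = source._pages.pages[index].asarray()
    intensity = _to_grayscale_unit(raw, source._nominal_max)
    time_s = index / source.fps if source.fps else None
    return Frame(index=index, time_s=time_s, intensity=intensity)


def calibrate_scale(known_length_um: float, measured_length_px: float) -> float:
    """Pixel scale (um/px) from an object of known physical length.

    The scale bar (or any feature of known size, e.g. the pipette outer
    diameter) measured once in pixels fixes the um/px ratio for the whole
    recording.
    """
    if not known_length_um > 0:
        raise ValueError(f"known length must be positive, got {known_length_um}")
    if not measured_length_px > 0:
        raise ValueError(f"measured length must be positive, got {measured_length_px}")
    return known_length_um / measured_length_px


class FrameBuffer:
    """Pre-read slice of a recording exposing the VideoSource frame interface.

    The analysis pipeline reads each frame exactly once per interval and hands
    the buffer to both trackers, halving decode work relative to letting each
    tracker pull frames independently.
    """

    def __init__(self, source: VideoSource, indices) -> None:
        self._frames = {i: source.get_frame(i) for i in indices}
        self.n_frames = source.n_frames
        self.height = source.height
        self.width = source.width
        self.fps = source.fps
        self.pixel_scale = source.pixel_scale
        self.path = source.path

    def get_frame(self, index: int) -> Frame:
        try:
            return self._frames[index]
        except KeyError:
            raise IndexError(f"frame {index} not in buffered interval") from None
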