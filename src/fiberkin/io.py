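"""Calibrated image sequences and TIFF I/O.

Movies are held as plain ``(frames, rows, cols)`` arrays with acquisition
calibration attached (pixel size in micrometres per pixel, frame interval in
seconds, camera exposure in seconds).  On disk a movie is a multi-page
grayscale TIFF plus an optional JSON sidecar carrying the calibration and,
for synthetic movies, the generator spec and ground truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageSequence", "read_movie", "write_movie", "MissingCalibrationWarning"]


class MissingCalibrationWarning(UserWarning):
    """Raised when a movie is loaded without physical calibration."""


@dataclass
class ImageSequence:
    """A time-lapse movie with physical calibration.

    Parameters
    ----------
    data : ndarray, shape (n_frames, n_rows, n_cols)
        Pixel intensities.  Rows run dorsal-to-ventral (image convention:
        row index increases downward/ventrally), columns rostral-to-caudal.
    pixel_size : float or None
        Micrometres per pixel; ``None`` means pixel-unit-only mode.
    frame_interval : float or None
        Seconds between consecutive frames.
    exposure : float or None
        Camera exposure per frame in seconds (used for instantaneous
        speeds of retracting cut ends).
    meta : dict
        Free-form provenance (generator spec, source path, ...).
    """

    data: np.ndarray
    pixel_size: float | None = None
    frame_interval: float | None = None
    exposure: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError(
                f"movie must be (frames, rows, cols); got shape {self.data.shape}"
            )
        for name in ("pixel_size", "frame_interval", "exposure"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def times(self) -> np.ndarray:
        """Frame start times in seconds (requires frame_interval)."""
        if self.frame_interval is None:
            raise ValueError("frame_interval not set")
        return np.arange(self.n_frames) * self.frame_interval

    def with_data(self, data: np.ndarray) -> "ImageSequence":
        """Copy of the sequence with the pixel data replaced."""
        return replace(self, data=np.asarray(data))

    def require_calibration(self) -> None:
        if self.pixel_size is None or self.frame_interval is None:
            raise ValueError(
                "operation requires pixel_size and frame_interval calibration"
            )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_movie(path, seq: ImageSequence, truth=None) -> Path:
    """Write a movie to a multi-page TIFF with a JSON sidecar.

    The sidecar stores calibration plus ``seq.meta`` and, if given, a
    JSON-serialisable ``truth`` record (ground truth of a generator).
    Returns the sidecar path.
    """
    path = Path(path)
    tifffile.imwrite(path, np.asarray(seq.data), photometric="minisblack")
    record = {
        "pixel_size_um": seq.pixel_size,
        "frame_interval_s": seq.frame_interval,
        "exposure_s": seq.exposure,
        "meta": _jsonable(seq.meta),
    }
    if truth is not None:
        record["truth"] = _jsonable(truth)
    side = _sidecar_path(path)
    side.write_text(json.dumps(record, indent=1))
    return side


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    return obj


def read_movie(path, pixel_size=None, frame_interval=None, exposure=None) -> ImageSequence:
    """Read a multi-page grayscale TIFF as an :class:`ImageSequence`.

    Calibration precedence: explicit arguments, then the JSON sidecar
    written by :func:`write_movie`.  If neither provides pixel size and
    frame interval the movie is returned in pixel-unit-only mode with an
    explicit warning.  Pages must share shape and dtype; a mixed or
    truncated file raises an error naming the offending page.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = tif.pages
        first = pages[0]
        shape0, dtype0 = first.shape, first.dtype
        frames = []
        for i, page in enumerate(pages):
            if page.shape != shape0 or page.dtype != dtype0:
                raise ValueError(
                    f"page {i} has shape {page.shape}/{page.dtype}, "
                    f"expected {shape0}/{dtype0}"
                )
            try:
                frames.append(page.asarray())
            except Exception as exc:  # truncated file
                raise ValueError(
                    f"could not read page {i} (last readable page {i - 1}): {exc}"
                ) from exc
    data = np.stack(frames)

    meta: dict = {"source": str(path)}
    side = _sidecar_path(path)
    if side.exists():
        record = json.loads(side.read_text())
        pixel_size = pixel_size or record.get("pixel_size_um")
        frame_interval = frame_interval or record.get("frame_interval_s")
        exposure = exposure or record.get("exposure_s")
        meta.update(record.get("meta") or {})
        if "truth" in record:
            meta["truth"] = record["truth"]
    if pixel_size is None or frame_interval is None:
        warnings.warn(
            "no pixel_size/frame_interval available: pixel-unit-only mode",
            MissingCalibrationWarning,
            stacklevel=2,
        )
    return ImageSequence(
        data, pixel_size=pixel_size, frame_interval=frame_interval,
        exposure=exposure, meta=meta,
    )
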