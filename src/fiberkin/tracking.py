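"""Sub-pixel tracking of a near-horizontal fluorescent fiber.

The tracker estimates, on every frame, a smooth curve x -> y(x) through
the intensity ridge of the fiber.  It proceeds in six steps:

1. global background subtraction from the whole-sequence histogram
   (mode I0, mean-below-mode I1, absolute deviation dev = I0 - I1;
   subtract I0 + dev and clip at zero);
2. anisotropic Gaussian pre-smoothing of each frame (wide along the
   fiber, narrow across it);
3. per-column integer argmax plus a clamped three-point parabolic
   refinement to sub-pixel precision;
4. per-column half-max width; columns wider than ``width_limit`` px are
   invalid (this rejects columns contaminated by bright cells);
5. normalized-convolution smoothing/extrapolation of the raw estimates:
   iterate  y := y_raw on the valid domain;  y := (y*G)/(1*G);
6. consistency rejection: valid columns whose raw estimate departs from
   the smooth curve by more than ``consistency_tol`` px are dropped and
   step 5 is re-run for the final curve.

Coordinates: columns x are 0-based integers along the rostrocaudal axis
(increasing caudal); y is continuous, 0-based, increasing ventral.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .io import ImageSequence

__all__ = [
    "BackgroundModel", "TrackerParams", "FiberTrace", "ColumnPeak",
    "estimate_background", "smooth_frame", "subpixel_offset",
    "column_peak_subpixel",
    "column_width_halfmax", "smooth_and_extrapolate", "reject_inconsistent",
    "track_sequence",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BackgroundModel:
    """Whole-sequence background statistics.

    ``i0`` is the histogram mode (typical background level), ``i1`` the
    mean of intensities below the mode, and ``dev = i0 - i1`` a robust
    absolute-deviation scale of the background.
    """

    i0: float
    i1: float

    @property
    def dev(self) -> float:
        return self.i0 - self.i1

    @property
    def threshold(self) -> float:
        """Subtraction level i0 + dev."""
        return self.i0 + self.dev


@dataclass(frozen=True)
class TrackerParams:
    sigma_x: float = 3.5          # px, pre-smoothing along the fiber
    sigma_y: float = 1.9          # px, pre-smoothing across the fiber
    smooth_sigma: float = 5.8     # px, normalized-convolution kernel
    n_iter: int = 100
    width_limit: float = 10.0     # px, half-max width validity cut
    consistency_tol: float = 1.0  # px, |y - y_raw| rejection threshold
    tol: float = 1e-6             # px, sup-norm convergence threshold

    def __post_init__(self):
        for name in ("sigma_x", "sigma_y", "smooth_sigma", "n_iter",
                     "width_limit", "consistency_tol", "tol"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def estimate_background(seq: ImageSequence) -> tuple[BackgroundModel, ImageSequence]:
    """Estimate and subtract the whole-sequence background level.

    The mode is taken over integer-quantized intensities (camera counts);
    ties take the smallest value.  The returned sequence is
    ``max(0, data - (i0 + dev))``.  An all-constant sequence has no
    values below the mode, so ``i1 := i0`` and ``dev = 0`` by convention.
    """
    data = np.asarray(seq.data, dtype=float)
    if data.size == 0:
        raise ValueError("empty sequence")
    q = np.rint(data).astype(np.int64).ravel()
    offset = q.min()
    counts = np.bincount(q - offset)
    i0 = float(np.argmax(counts) + offset)  # argmax -> smallest on ties
    below = data[data < i0]
    if below.size == 0:
        i1 = i0
        log.info("no intensities below the mode; dev set to 0")
    else:
        i1 = float(below.mean())
    model = BackgroundModel(i0=i0, i1=i1)
    out = np.clip(data - model.threshold, 0.0, None)
    return model, seq.with_data(out)


def smooth_frame(frame: np.ndarray, sigma_x: float, sigma_y: float) -> np.ndarray:
    """Anisotropic Gaussian blur (reflective boundaries)."""
    if sigma_x <= 0 or sigma_y <= 0:
        raise ValueError("sigma_x and sigma_y must be positive")
    return gaussian_filter(np.asarray(frame, float), sigma=(sigma_y, sigma_x),
                           mode="reflect")


class ColumnPeak(NamedTuple):
    y0: int          # integer argmax row
    y_raw: float     # sub-pixel refinement (NaN if invalid)
    valid: bool


def subpixel_offset(i_minus: float, i_0: float, i_plus: float) -> float:
    """Clamped parabolic offset from three samples around a peak.

    offset = clamp(-1, 1, (I+ - I-) / (4 I0 - 2 I- - 2 I+)); a flat or
    degenerate peak (denominator <= 0, e.g. an exact plateau) keeps
    offset 0 by convention.
    """
    den = 4 * i_0 - 2 * i_minus - 2 * i_plus
    if den <= 0:
        return 0.0
    return float(np.clip((i_plus - i_minus) / den, -1.0, 1.0))


def column_peak_subpixel(column: np.ndarray) -> ColumnPeak:
    """Integer argmax with clamped parabolic sub-pixel refinement.

    y_raw = y0 + clamp(-1, 1, (I[y0+1] - I[y0-1]) /
                               (4 I[y0] - 2 I[y0-1] - 2 I[y0+1])).
    A flat or degenerate peak (denominator <= 0) keeps offset 0.  A
    boundary argmax, or an all-zero column, is invalid.
    """
    col = np.asarray(column, dtype=float)
    if col.ndim != 1 or col.size < 3:
        raise ValueError("column must be a 1-D vector of length >= 3")
    y0 = int(np.argmax(col))
    if col[y0] <= 0 or y0 == 0 or y0 == col.size - 1:
        return ColumnPeak(y0, float("nan"), False)
    offset = subpixel_offset(col[y0 - 1], col[y0], col[y0 + 1])
    return ColumnPeak(y0, y0 + offset, True)


def column_width_halfmax(column: np.ndarray, width_limit: float = 10.0):
    """Half-max width of a column and its validity flag.

    The width is the extent (diameter) of the set of rows whose intensity
    reaches half the column maximum; a column is valid when the width is
    strictly below ``width_limit``.  Two separate bright objects inflate
    the extent and invalidate the column, which is the point.
    """
    col = np.asarray(column, dtype=float)
    m = col.max()
    if m <= 0:
        return float("nan"), False
    idx = np.nonzero(col >= 0.5 * m)[0]
    width = float(idx[-1] - idx[0] + 1)
    return width, width < width_limit


def _normalized_smooth(y: np.ndarray, sigma: float) -> np.ndarray:
    num = gaussian_filter1d(y, sigma, mode="constant", cval=0.0)
    den = gaussian_filter1d(np.ones_like(y), sigma, mode="constant", cval=0.0)
    return num / den


def smooth_and_extrapolate(y_raw: np.ndarray, valid: np.ndarray,
                           smooth_sigma: float = 5.8, n_iter: int = 100,
                           tol: float = 1e-6) -> np.ndarray:
    """Iterative normalized-convolution smoothing of the raw estimates.

    Alternates (a) resetting y to y_raw on the valid domain and
    (b) y := (y*G)/(1*G) with a Gaussian kernel G, until the sup-norm
    update falls below ``tol`` px or ``n_iter`` iterations.  The division
    by (1*G) intrinsically corrects image-edge attenuation, and the
    iteration extrapolates the curve outside the valid domain.
    """
    y_raw = np.asarray(y_raw, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    if valid.shape != y_raw.shape:
        raise ValueError("valid mask and y_raw must share shape")
    if not valid.any():
        raise ValueError("empty valid domain: frame untracked")
    y = np.full_like(y_raw, y_raw[valid].mean())
    y[valid] = y_raw[valid]
    for _ in range(int(n_iter)):
        y_prev = y
        y = y.copy()
        y[valid] = y_raw[valid]
        y = _normalized_smooth(y, smooth_sigma)
        if np.max(np.abs(y - y_prev)) < tol:
            break
    return y


def reject_inconsistent(y: np.ndarray, y_raw: np.ndarray, valid: np.ndarray,
                        consistency_tol: float = 1.0) -> np.ndarray:
    """Drop valid columns where |y - y_raw| exceeds the tolerance.

    The inequality is strict ("larger than"): a deviation exactly equal
    to the tolerance is retained.
    """
    y = np.asarray(y, float)
    y_raw = np.asarray(y_raw, float)
    valid = np.asarray(valid, bool)
    keep = valid & ~(np.abs(y - y_raw) > consistency_tol)
    return keep


def _frame_peaks(frame: np.ndarray):
    """Vectorized per-column argmax + parabolic refinement + half-max width."""
    h, w = frame.shape
    y0 = np.argmax(frame, axis=0)
    cols = np.arange(w)
    peak = frame[y0, cols]
    interior = (y0 > 0) & (y0 < h - 1) & (peak > 0)
    ym = frame[np.clip(y0 - 1, 0, h - 1), cols]
    yp = frame[np.clip(y0 + 1, 0, h - 1), cols]
    den = 4 * peak - 2 * ym - 2 * yp
    with np.errstate(divide="ignore", invalid="ignore"):
        offset = np.clip((yp - ym) / den, -1.0, 1.0)
    offset = np.where(den > 0, offset, 0.0)
    y_raw = np.where(interior, y0 + offset, np.nan)

    above = frame >= 0.5 * np.where(peak > 0, peak, np.inf)[None, :]
    any_above = above.any(axis=0)
    first = above.argmax(axis=0)
    last = h - 1 - above[::-1].argmax(axis=0)
    width = np.where(any_above, (last - first + 1).astype(float), np.nan)
    return y0, y_raw, width, interior


@dataclass
class FiberTrace:
    """Per-frame sub-pixel centerline of the fiber.

    Arrays are ``(n_frames, n_cols)``; ``valid`` is the final column
    domain after the width and consistency rules, ``tracked`` flags
    frames where any column survived.  ``y`` is defined for every column
    (extrapolated outside the valid domain).
    """

    y: np.ndarray           # final smooth curve, px
    y_raw: np.ndarray       # step-3 raw estimates, px (NaN where no peak)
    y0: np.ndarray          # integer argmax, px
    width: np.ndarray       # half-max width, px
    valid: np.ndarray       # bool, final valid domain
    tracked: np.ndarray     # bool per frame
    background: BackgroundModel
    params: TrackerParams
    pixel_size: float | None = None
    frame_interval: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.y.shape[0]

    @property
    def n_cols(self) -> int:
        return self.y.shape[1]

    @property
    def y_um(self) -> np.ndarray:
        if self.pixel_size is None:
            raise ValueError("pixel_size calibration required for y_um")
        return self.y * self.pixel_size

    @property
    def x_um(self) -> np.ndarray:
        if self.pixel_size is None:
            raise ValueError("pixel_size calibration required for x_um")
        return np.arange(self.n_cols) * self.pixel_size

    def to_dataframe(self) -> pd.DataFrame:
        """Long table: frame, x_px, y_px, (y_um), valid."""
        f, x = np.meshgrid(np.arange(self.n_frames), np.arange(self.n_cols),
                           indexing="ij")
        out = pd.DataFrame({
            "frame": f.ravel(), "x_px": x.ravel(), "y_px": self.y.ravel(),
            "valid": self.valid.ravel(),
        })
        if self.pixel_size is not None:
            out["x_um"] = out["x_px"] * self.pixel_size
            out["y_um"] = out["y_px"] * self.pixel_size
        return out

    def plot(self, frame: int = 0, ax=None):
        """Plot the tracked curve of one frame."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(self.n_cols)
        ax.plot(x, self.y[frame], label=f"frame {frame}")
        ax.plot(x[self.valid[frame]], self.y_raw[frame][self.valid[frame]],
                ".", ms=2, label="raw (valid)")
        ax.invert_yaxis()
        ax.set_xlabel("x (px, rostral to caudal)")
        ax.set_ylabel("y (px, dorsal to ventral)")
        ax.legend()
        return ax


def track_sequence(seq: ImageSequence,
                   params: TrackerParams | None = None) -> FiberTrace:
    """Run the full six-step tracker on a movie.

    Frames where every column is rejected are flagged untracked (their
    curve is NaN) and never silently interpolated.
    """
    params = params or TrackerParams()
    model, sub = estimate_background(seq)
    n_frames, h, w = sub.shape

    y = np.full((n_frames, w), np.nan)
    y_raw_all = np.full((n_frames, w), np.nan)
    y0_all = np.zeros((n_frames, w), dtype=int)
    width_all = np.full((n_frames, w), np.nan)
    valid_all = np.zeros((n_frames, w), dtype=bool)
    tracked = np.zeros(n_frames, dtype=bool)

    for i in range(n_frames):
        sm = smooth_frame(sub.data[i], params.sigma_x, params.sigma_y)
        y0, y_raw, width, has_peak = _frame_peaks(sm)
        valid = has_peak & (width < params.width_limit)
        y0_all[i], y_raw_all[i], width_all[i] = y0, y_raw, width
        if not valid.any():
            log.warning("frame %d untracked: no valid columns", i)
            continue
        yi = smooth_and_extrapolate(y_raw, valid, params.smooth_sigma,
                                    params.n_iter, params.tol)
        valid2 = reject_inconsistent(yi, y_raw, valid, params.consistency_tol)
        if not valid2.any():
            log.warning("frame %d untracked: all columns inconsistent", i)
            continue
        y[i] = smooth_and_extrapolate(y_raw, valid2, params.smooth_sigma,
                                      params.n_iter, params.tol)
        valid_all[i] = valid2
        tracked[i] = True

    return FiberTrace(
        y=y, y_raw=y_raw_all, y0=y0_all, width=width_all, valid=valid_all,
        tracked=tracked, background=model, params=params,
        pixel_size=seq.pixel_size, frame_interval=seq.frame_interval,
        meta=dict(seq.meta),
    )
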