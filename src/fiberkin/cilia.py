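"""Orientation, beat frequency and clustering of motile cilia.

Cilia lining the central canal are analysed one at a time from a mask
isolating a single cilium.  The orientation is the principal axis of the
thresholded temporal-mean blob, expressed in degrees from the horizontal
with 0 deg pointing caudal: ventral-wall cilia use a signed convention
(-90..+90, positive = caudal tilt), dorsal-wall cilia the folded 0..90
convention.  The main beat frequency is estimated by counting
oscillations (upward mean crossings) of the fluorescence trace inside a
region of interest, cross-checked against the dominant spectral peak;
at 40 Hz sampling frequencies are only observable up to the 20 Hz
Nyquist ceiling, and estimates at the ceiling carry an aliasing flag.

The deterministic two-cluster k-means used to dichotomize image patches
(fiber up/down) initializes the centers with the first two patches and
alternates assignment/update until the labels stabilize, so identical
input order gives identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from scipy import stats
from skimage import measure

from .io import ImageSequence

__all__ = [
    "PatchClustering", "BeatFrequency", "FisherOrientationTest",
    "trace_from_movie", "cilium_orientation", "beat_frequency",
    "polarity_class", "kmeans2", "orientation_vs_fiber", "sweep_mask",
]

log = logging.getLogger(__name__)


def trace_from_movie(seq: ImageSequence, mask: np.ndarray) -> np.ndarray:
    """Mean intensity inside a boolean mask, per frame."""
    mask = np.asarray(mask, bool)
    if mask.shape != seq.shape[1:]:
        raise ValueError("mask shape must match frame shape")
    if not mask.any():
        raise ValueError("empty mask")
    return seq.data[:, mask].mean(axis=1)


def sweep_mask(shape: tuple[int, int], base_px: tuple[float, float],
               mean_angle_deg: float, length_px: float,
               wall: str) -> np.ndarray:
    """ROI covering the half of a cilium's sweep above its mean angle.

    The mean intensity inside this region rises and falls once per beat
    cycle (the cilium enters and leaves it once per period), which is
    the smooth periodic signal the oscillation-counting frequency
    estimator needs; a tiny tip ROI would be occupied too briefly per
    cycle at 40 Hz sampling.
    """
    if wall not in ("dorsal", "ventral"):
        raise ValueError("wall must be 'dorsal' or 'ventral'")
    h, w = shape
    bx, by = base_px
    rows, cols = np.mgrid[0:h, 0:w]
    canal = -1.0 if wall == "ventral" else 1.0
    ang = np.degrees(np.arctan2(canal * (rows - by), cols - bx))
    r = np.hypot(rows - by, cols - bx)
    return (ang > mean_angle_deg) & (r < length_px)


def _principal_axis(image: np.ndarray, mask: np.ndarray):
    """Intensity-weighted principal axis (unit vector) of a blob."""
    rows, cols = np.nonzero(mask)
    wts = image[rows, cols].astype(float)
    wts = np.clip(wts, 0, None)
    if wts.sum() <= 0:
        wts = np.ones_like(wts)
    rc = np.average(rows, weights=wts)
    cc = np.average(cols, weights=wts)
    dr, dc = rows - rc, cols - cc
    cov = np.array([
        [np.average(dc * dc, weights=wts), np.average(dc * dr, weights=wts)],
        [np.average(dc * dr, weights=wts), np.average(dr * dr, weights=wts)],
    ])
    vals, vecs = np.linalg.eigh(cov)
    axis = vecs[:, np.argmax(vals)]      # (d_col, d_row)
    return axis, (rc, cc)


def cilium_orientation(seq_or_image, mask: np.ndarray, wall: str) -> float:
    """Orientation (deg from horizontal, 0 deg caudal) of one cilium.

    ``seq_or_image`` may be a movie (its temporal mean is used) or a
    single image.  The blob is the masked region thresholded at half its
    maximum; it must be one connected component.  The principal axis is
    oriented into the canal (up from the ventral wall, down from the
    dorsal wall) and mapped to the wall's angle convention.
    """
    if wall not in ("dorsal", "ventral"):
        raise ValueError("wall must be 'dorsal' or 'ventral'")
    if isinstance(seq_or_image, ImageSequence):
        image = seq_or_image.data.mean(axis=0)
    else:
        image = np.asarray(seq_or_image, dtype=float)
    mask = np.asarray(mask, bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape must match image shape")
    region = np.where(mask, image, 0.0)
    m = region.max()
    if m <= 0:
        raise ValueError("empty mask region")
    blob = region >= 0.5 * m
    labels = measure.label(blob)
    n = int(labels.max())
    if n == 0:
        raise ValueError("no blob above half max in the mask")
    if n > 1:
        raise ValueError(f"mask region has {n} components; isolate one cilium")

    (d_col, d_row), _ = _principal_axis(region, blob)
    canal_sign = -1.0 if wall == "ventral" else 1.0   # rows grow ventral
    v_canal = canal_sign * d_row
    u_caudal = d_col
    if v_canal < 0:                                   # orient into the canal
        v_canal, u_caudal = -v_canal, -u_caudal
    raw = np.degrees(np.arctan2(v_canal, u_caudal))   # [0, 180]
    if wall == "ventral":
        theta = raw if raw <= 90 else raw - 180.0     # signed, caudal positive
    else:
        theta = raw if raw <= 90 else 180.0 - raw     # folded 0..90
    return float(theta)


@dataclass
class BeatFrequency:
    frequency_hz: float          # oscillation count per second
    spectral_peak_hz: float      # dominant periodogram frequency (audit)
    nyquist_hz: float
    low_confidence: bool = False
    aliasing_warning: bool = False

    def summary(self) -> str:
        s = (f"main beat frequency {self.frequency_hz:.2f} Hz "
             f"(spectral peak {self.spectral_peak_hz:.2f} Hz, "
             f"Nyquist {self.nyquist_hz:.1f} Hz)")
        if self.low_confidence:
            s += " [low confidence]"
        if self.aliasing_warning:
            s += " [at Nyquist ceiling: possible aliasing]"
        return s


def beat_frequency(trace: np.ndarray, rate: float) -> BeatFrequency:
    """Main beat frequency by oscillation counting, in Hz.

    The trace is linearly detrended; the frequency is the number of
    upward mean crossings divided by the duration.  A periodogram peak
    is reported alongside for audit.  A flat trace returns 0 Hz with a
    low-confidence flag; an estimate within 2% of the Nyquist ceiling
    carries an aliasing warning.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or trace.size < 4:
        raise ValueError("trace must be a 1-D series with >=4 samples")
    if rate <= 0:
        raise ValueError("rate must be positive")
    nyquist = rate / 2.0
    duration = trace.size / rate

    x = sp_signal.detrend(trace)
    scale = np.std(x)
    if scale == 0 or scale < 1e-12 * max(1.0, abs(trace).max()):
        return BeatFrequency(0.0, 0.0, nyquist, low_confidence=True)

    pos = x > 0
    up = np.count_nonzero(~pos[:-1] & pos[1:])
    freq = up / duration

    f, p = sp_signal.periodogram(x, fs=rate)
    peak = float(f[1:][np.argmax(p[1:])]) if f.size > 1 else 0.0

    return BeatFrequency(
        frequency_hz=float(freq),
        spectral_peak_hz=peak,
        nyquist_hz=nyquist,
        aliasing_warning=freq >= 0.98 * nyquist,
    )


def polarity_class(theta_deg: float, wall: str, z_flag: bool = False,
                   vertical_band_deg: float = 80.0) -> str:
    """Polarity class of a cilium: 'caudal', 'dorsal' or 'z-plane'.

    A cilium beating out of the sagittal plane (``z_flag``) is
    'z-plane'; one within ``vertical_band_deg`` of the vertical is
    polarized 'dorsal'; the rest tilt toward the caudal end.
    """
    if wall not in ("dorsal", "ventral"):
        raise ValueError("wall must be 'dorsal' or 'ventral'")
    if z_flag:
        return "z-plane"
    return "dorsal" if abs(theta_deg) >= vertical_band_deg else "caudal"


@dataclass
class PatchClustering:
    """Two-cluster partition of image patches."""

    labels: np.ndarray           # 0/1 per patch
    centers: np.ndarray          # (2, n_pixels)
    inertia: float               # within-cluster sum of squares

    def partition(self) -> frozenset:
        """Order-free representation {frozenset(indices), ...}."""
        return frozenset(
            frozenset(np.nonzero(self.labels == k)[0].tolist())
            for k in (0, 1) if np.any(self.labels == k)
        )


def kmeans2(patches: np.ndarray, max_iter: int = 200) -> PatchClustering:
    """Deterministic two-cluster k-means on flattened patches.

    Centers are initialized to the first two patches (so the result is a
    function of the input order alone); assignment and center update
    alternate until the labels stop changing.  If the first two patches
    coincide, the second center is re-seeded to the patch farthest from
    the first.
    """
    X = np.asarray(patches, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    elif X.ndim > 2:
        X = X.reshape(X.shape[0], -1)
    p = X.shape[0]
    if p < 2:
        raise ValueError("need at least 2 patches")
    centers = X[:2].copy()
    if np.allclose(centers[0], centers[1]):
        far = int(np.argmax(((X - centers[0]) ** 2).sum(axis=1)))
        centers[1] = X[far]
        log.info("duplicate initial centers: re-seeded second center to "
                 "patch %d", far)
    labels = np.full(p, -1)
    for _ in range(max_iter):
        d = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new = np.argmin(d, axis=1)
        if np.array_equal(new, labels):
            break
        labels = new
        for k in (0, 1):
            if np.any(labels == k):
                centers[k] = X[labels == k].mean(axis=0)
    inertia = float(((X - centers[labels]) ** 2).sum())
    return PatchClustering(labels=labels, centers=centers, inertia=inertia)


@dataclass
class FisherOrientationTest:
    table: np.ndarray            # 2x2: (steep/shallow) x (fiber up/down)
    odds_ratio: float
    p_value: float
    mean_theta_by_label: dict

    def summary(self) -> str:
        return (f"Fisher exact (two-sided) p = {self.p_value:.4g}; "
                f"mean orientation by fiber position: "
                + ", ".join(f"{k}: {v:.1f} deg"
                            for k, v in self.mean_theta_by_label.items()))


def orientation_vs_fiber(theta_deg: np.ndarray,
                         fiber_labels: np.ndarray) -> FisherOrientationTest:
    """Association between cilium orientation and fiber up/down position.

    Per-frame orientations are dichotomized at the per-cilium median
    (steep vs shallow) and crossed with the fiber position labels in a
    2x2 table tested with Fisher's exact test (two-sided).
    """
    theta = np.asarray(theta_deg, dtype=float)
    labels = np.asarray(fiber_labels)
    if theta.shape != labels.shape:
        raise ValueError("theta and labels must align frame by frame")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("need exactly two fiber position classes present")
    steep = theta > np.median(theta)
    table = np.array([
        [np.sum(steep & (labels == c)) for c in classes],
        [np.sum(~steep & (labels == c)) for c in classes],
    ])
    res = stats.fisher_exact(table, alternative="two-sided")
    means = {str(c): float(theta[labels == c].mean()) for c in classes}
    return FisherOrientationTest(
        table=table, odds_ratio=float(res[0]), p_value=float(res[1]),
        mean_theta_by_label=means,
    )
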