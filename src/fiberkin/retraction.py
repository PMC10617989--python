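"""Kinematics of the cut-fiber ends after photoablation.

After a focal laser cut the two ends of the taut fiber recede from the
ablation locus.  This module locates the ends frame by frame, computes
instantaneous and windowed speeds, fits the retraction distance against
sqrt(time) (the signature of stress diffusion along the fiber), groups
fibers into fast/slow retraction classes, and estimates the elongation
dL from the retention position of ends that stop inside the field of
view.

The first 50 ms after the cut are excluded from fits and speed windows:
the laser pulse leaves transient imaging artifacts there, and the
initial-speed window is taken at 50-75 ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter

from .io import ImageSequence
from .tracking import estimate_background

__all__ = [
    "RetractionTrace", "EndKinematics", "SqrtTimeFit", "DeltaLEstimate",
    "RetractionClasses", "detect_ends", "instantaneous_speed",
    "speed_metrics", "sqrt_time_fit", "detect_retention",
    "classify_retraction", "estimate_delta_L", "ARTIFACT_WINDOW_S",
]

ARTIFACT_WINDOW_S = 0.050    # s after the cut excluded (laser artifacts)
INITIAL_SPEED_WINDOW_S = (0.050, 0.075)
ENDS = ("rostral", "caudal")


@dataclass
class RetractionTrace:
    """Per-frame cut-end positions relative to the ablation.

    ``time_s`` counts from the ablation (strictly increasing); end
    positions are um along the rostrocaudal axis, NaN once censored
    (out of the field of view).
    """

    time_s: np.ndarray
    rostral_x_um: np.ndarray
    caudal_x_um: np.ndarray
    ablation_locus_x_um: float
    exposure_s: float = 0.025
    field_width_um: float | None = None
    retention_position_um: dict = field(default_factory=dict)  # per end
    flower_observed: bool = False

    def __post_init__(self):
        t = np.asarray(self.time_s, float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        self.time_s = t
        self.rostral_x_um = np.asarray(self.rostral_x_um, float)
        self.caudal_x_um = np.asarray(self.caudal_x_um, float)

    def end_positions(self, end: str) -> np.ndarray:
        if end not in ENDS:
            raise ValueError(f"end must be one of {ENDS}")
        return self.rostral_x_um if end == "rostral" else self.caudal_x_um

    def distances(self, end: str) -> np.ndarray:
        """Retraction distance |end - locus| in um (NaN where censored)."""
        return np.abs(self.end_positions(end) - self.ablation_locus_x_um)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time_s,
            "rostral_x_um": self.rostral_x_um,
            "caudal_x_um": self.caudal_x_um,
            "rostral_dist_um": self.distances("rostral"),
            "caudal_dist_um": self.distances("caudal"),
        })


def detect_ends(seq: ImageSequence, ablation_frame: int, locus_x_um: float,
                exposure_s: float | None = None) -> RetractionTrace:
    """Locate the receding cut ends on each post-ablation frame.

    The movie must be pre-rotated so the fiber is horizontal.  Each
    frame's per-column fiber signal is the row-maximum of the
    background-subtracted, lightly smoothed image; an end is the extreme
    column toward the ablation gap whose signal still exceeds half the
    pre-ablation ridge intensity, refined to sub-column precision by
    linear interpolation of the threshold crossing.  Ends that leave the
    field of view are censored (NaN) from that frame on.
    """
    seq.require_calibration()
    if not 0 < ablation_frame < seq.n_frames:
        raise ValueError("ablation_frame must be inside the movie, after "
                         "at least one pre-cut frame")
    _, sub = estimate_background(seq)
    px = seq.pixel_size
    locus_px = locus_x_um / px
    n, h, w = sub.shape

    signal = np.empty((n, w))
    for i in range(n):
        signal[i] = gaussian_filter(sub.data[i], 1.0, mode="reflect").max(axis=0)

    pre = signal[:ablation_frame]
    ridge = float(np.median(pre.max(axis=1)))
    if ridge <= 0:
        raise ValueError("no fiber signal before the ablation frame")
    thr = 0.5 * ridge

    def crossing(s: np.ndarray, side: str) -> float:
        above = np.nonzero(s >= thr)[0]
        if side == "rostral":
            cand = above[above <= locus_px + 1]
            if cand.size == 0:
                return np.nan
            j = cand[-1]
            if j + 1 < w and s[j + 1] < thr and s[j] > s[j + 1]:
                return j + (s[j] - thr) / (s[j] - s[j + 1])
            return float(j)
        cand = above[above >= locus_px - 1]
        if cand.size == 0:
            return np.nan
        j = cand[0]
        if j - 1 >= 0 and s[j - 1] < thr and s[j] > s[j - 1]:
            return j - (s[j] - thr) / (s[j] - s[j - 1])
        return float(j)

    n_post = n - ablation_frame
    t = np.arange(n_post) * seq.frame_interval
    rostral = np.full(n_post, np.nan)
    caudal = np.full(n_post, np.nan)
    gone = {"rostral": False, "caudal": False}
    for k in range(n_post):
        s = signal[ablation_frame + k]
        for end, arr in (("rostral", rostral), ("caudal", caudal)):
            if gone[end]:
                continue
            pos = crossing(s, end)
            if np.isnan(pos):
                gone[end] = True     # censored from this frame on
            else:
                arr[k] = pos * px

    exposure = exposure_s or seq.exposure or seq.frame_interval
    trace = RetractionTrace(
        time_s=t, rostral_x_um=rostral, caudal_x_um=caudal,
        ablation_locus_x_um=locus_x_um, exposure_s=exposure,
        field_width_um=w * px,
    )
    for end in ENDS:
        r = detect_retention(trace, end)
        if r is not None:
            trace.retention_position_um[end] = r
    return trace


def instantaneous_speed(trace: RetractionTrace, end: str):
    """Frame-pair speeds |dx| / exposure, um/s.

    Returns ``(t_mid, speeds)``; pairs spanning a censored position are
    NaN rather than fabricated.
    """
    x = trace.end_positions(end)
    if np.sum(~np.isnan(x)) < 2:
        raise ValueError("need >=2 uncensored frames")
    dx = np.abs(np.diff(x))
    v = dx / trace.exposure_s
    t_mid = 0.5 * (trace.time_s[1:] + trace.time_s[:-1])
    return t_mid, v


@dataclass
class EndKinematics:
    initial_speed_um_s: float | None   # distance accrued in 50-75 ms / 25 ms
    max_speed_um_s: float | None


def speed_metrics(trace: RetractionTrace, end: str,
                  window_s=INITIAL_SPEED_WINDOW_S) -> EndKinematics:
    """Initial-window and maximum retraction speeds of one end.

    The initial speed is the retraction distance accrued over the
    50-75 ms window divided by its 25 ms span (positions interpolated
    to the window edges); the maximum is over instantaneous speeds after
    the artifact window.  Both are None where the data do not cover them.
    """
    d = trace.distances(end)
    t = trace.time_s
    ok = ~np.isnan(d)

    initial = None
    t0, t1 = window_s
    if ok.any() and t[ok].min() <= t0 and t[ok].max() >= t1:
        d0, d1 = np.interp([t0, t1], t[ok], d[ok])
        initial = float((d1 - d0) / (t1 - t0))

    max_speed = None
    try:
        t_mid, v = instantaneous_speed(trace, end)
    except ValueError:
        return EndKinematics(initial, None)
    sel = (t_mid > ARTIFACT_WINDOW_S) & ~np.isnan(v)
    if sel.any():
        max_speed = float(np.max(v[sel]))
    return EndKinematics(initial, max_speed)


@dataclass
class SqrtTimeFit:
    """Least-squares fit of retraction distance on sqrt(time)."""

    slope_um_per_sqrt_s: float
    intercept_um: float
    r_squared: float
    stderr: float
    n_points: int
    end: str

    def summary(self) -> str:
        return (f"{self.end} end: distance = "
                f"{self.slope_um_per_sqrt_s:.3g} sqrt(t) "
                f"{self.intercept_um:+.3g} um "
                f"(R^2 = {self.r_squared:.4f}, n = {self.n_points})")

    def plot(self, trace: RetractionTrace, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = trace.distances(self.end)
        rt = np.sqrt(trace.time_s)
        ax.plot(rt, d, "o", ms=3)
        xs = np.linspace(0, np.nanmax(rt), 50)
        ax.plot(xs, self.intercept_um + self.slope_um_per_sqrt_s * xs, "-")
        ax.set_xlabel("sqrt(time since cut) (sqrt(s))")
        ax.set_ylabel("retraction distance (um)")
        return ax


def sqrt_time_fit(trace: RetractionTrace, end: str,
                  min_time_s: float = ARTIFACT_WINDOW_S,
                  stop_at_retention: bool = True) -> SqrtTimeFit:
    """Fit distance = alpha sqrt(t) + b over the moving, artifact-free part.

    Points with t <= ``min_time_s`` are excluded; if the end is retained
    (stops inside the field of view) the fit stops at the retention time.
    """
    d = trace.distances(end)
    t = trace.time_s
    sel = (t > min_time_s) & ~np.isnan(d)
    if stop_at_retention:
        ret = detect_retention(trace, end)
        if ret is not None:
            sel &= t <= ret["time_s"]
    if sel.sum() < 3:
        raise ValueError("need >=3 uncensored points after the artifact window")
    res = stats.linregress(np.sqrt(t[sel]), d[sel])
    return SqrtTimeFit(
        slope_um_per_sqrt_s=float(res.slope),
        intercept_um=float(res.intercept),
        r_squared=float(res.rvalue**2),
        stderr=float(res.stderr),
        n_points=int(sel.sum()),
        end=end,
    )


def detect_retention(trace: RetractionTrace, end: str,
                     speed_threshold_um_s: float = 2.0,
                     min_frames: int = 10) -> dict | None:
    """Detect an end that stops inside the field of view.

    Retention is declared at the first frame from which the
    instantaneous speed stays below ``speed_threshold_um_s`` for at
    least ``min_frames`` consecutive frames; the retention position is
    the mean position over that run.
    """
    x = trace.end_positions(end)
    if np.sum(~np.isnan(x)) < min_frames + 1:
        return None
    v = np.abs(np.diff(x)) / np.diff(trace.time_s)
    slow = (v < speed_threshold_um_s) & ~np.isnan(v)
    run = 0
    for i, s in enumerate(slow):
        run = run + 1 if s else 0
        if run >= min_frames:
            start = i - run + 1
            return {
                "time_s": float(trace.time_s[start]),
                "position_um": float(np.nanmean(x[start:i + 2])),
            }
    return None


@dataclass
class RetractionClasses:
    labels: list[str]                  # "fast" / "slow" per fiber
    centers_um_per_sqrt_s: dict       # class -> geometric-mean slope


def classify_retraction(slopes) -> RetractionClasses:
    """Group fibers into fast/slow retraction by k-means on log slope.

    Uses the deterministic two-cluster k-means (centers initialized to
    the first two observations); the log scale reflects the order-of-
    magnitude separation between the two regimes.
    """
    from .cilia import kmeans2

    slopes = np.asarray(slopes, dtype=float)
    if slopes.ndim != 1 or slopes.size < 2:
        raise ValueError("need at least 2 fibers to classify")
    if np.any(slopes <= 0):
        raise ValueError("slopes must be positive")
    if np.all(slopes == slopes[0]):
        warnings.warn("all slopes equal: single class")
        return RetractionClasses(
            labels=["fast"] * slopes.size,
            centers_um_per_sqrt_s={"fast": float(slopes[0])})
    clu = kmeans2(np.log(slopes)[:, None])
    centers = np.exp(clu.centers[:, 0])
    fast_cluster = int(np.argmax(centers))
    labels = ["fast" if lab == fast_cluster else "slow" for lab in clu.labels]
    return RetractionClasses(
        labels=labels,
        centers_um_per_sqrt_s={
            "fast": float(centers[fast_cluster]),
            "slow": float(centers[1 - fast_cluster]),
        },
    )


@dataclass
class DeltaLEstimate:
    """Fiber elongation from the retention position, or a censored bound."""

    value_um: float | None
    lower_bound_um: float | None = None

    @property
    def is_bound(self) -> bool:
        return self.value_um is None

    def __str__(self) -> str:
        if self.is_bound:
            return f"dL > {self.lower_bound_um:.1f} um (end left field of view)"
        return f"dL = {self.value_um:.1f} um"


def estimate_delta_L(retention_position_um: float | None,
                     ablation_locus_um: float,
                     field_width_um: float | None = None) -> DeltaLEstimate:
    """Elongation dL = |retention position - ablation locus| per end.

    When the end never stops inside the field of view, dL is only
    lower-bounded by the field half-width (the least distance the end
    must have travelled on its side), reported as a censored bound.
    """
    if retention_position_um is not None:
        return DeltaLEstimate(abs(retention_position_um - ablation_locus_um))
    if field_width_um is None:
        raise ValueError("need field_width_um to bound dL without retention")
    return DeltaLEstimate(None, lower_bound_um=field_width_um / 2.0)
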