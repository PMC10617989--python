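"""Seeded synthetic-movie and trace generators with ground truth.

These generators emulate the statistical structure of sagittal-plane
fluorescence recordings of the central canal of larval zebrafish:

* a bright, near-horizontal Reissner fiber whose ~100 nm radius is well
  below the diffraction limit, so its image cross-section is a Gaussian
  (PSF-limited) ridge over a noisy background, optionally with bright
  cell-sized blobs;
* dorsoventral oscillation of the fiber with an amplitude profile that
  may be graded along the rostrocaudal (x) axis;
* post-ablation retraction of the two cut ends following the stress-
  diffusion law X(t) = c * sqrt(D t) * (dL/L);
* beating cilia modelled as anchored segments pivoting about their base;
* calcium (dF/F) traces with baseline drift, Gaussian noise and smooth
  transient events.

Every generator takes a frozen spec carrying its own ``seed`` and returns
the rendered data together with the ground truth, so each downstream
analysis stage can be tested by round trip without any real recording.
Identical spec (including seed) gives bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .io import ImageSequence

__all__ = [
    "FiberMovieSpec",
    "RetractionMovieSpec",
    "CiliumMovieSpec",
    "CalciumTraceSpec",
    "make_fiber_movie",
    "make_retraction_movie",
    "make_cilium_movie",
    "make_calcium_traces",
    "retraction_law_um",
]

# Typical 40x camera sampling; real recordings must supply their own value.
DEFAULT_PIXEL_SIZE_UM = 0.1625
DEFAULT_FRAME_INTERVAL_S = 0.025  # 40 Hz


def _check_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value}")


@dataclass(frozen=True)
class FiberMovieSpec:
    """Rendering and motion parameters of a synthetic fiber movie.

    Intensities are arbitrary camera counts.  ``oscillation_amplitude``
    (um) may be a scalar, a per-column array, or a callable of the
    rostrocaudal position in um, to emulate amplitude graded along the
    body axis.  ``curvature`` sets a slow quadratic bow of the resting
    centerline (um^-1).  ``blob_rate`` is the expected number of bright
    cell-like blobs per frame, exercising the width-based column
    rejection of the tracker.
    """

    n_frames: int = 200
    frame_interval: float = DEFAULT_FRAME_INTERVAL_S
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    width_px: int = 600
    height_px: int = 92
    fiber_profile_sigma: float = 1.5      # px, PSF-limited ridge width
    fiber_peak: float = 400.0
    background_level: float = 100.0
    background_noise_sd: float = 8.0
    oscillation_amplitude: float | Sequence[float] | Callable = 0.125  # um
    oscillation_frequency: float = 7.3    # Hz
    oscillation_phase: float | None = None  # rad; None -> drawn from seed
    curvature: float = 2e-4               # um^-1
    blob_rate: float = 0.0                # blobs / frame
    blob_sigma_px: float = 3.0
    seed: int = 0
    allow_aliasing: bool = False

    def validate(self) -> None:
        _check_positive(
            n_frames=self.n_frames, frame_interval=self.frame_interval,
            pixel_size=self.pixel_size, width_px=self.width_px,
            height_px=self.height_px, fiber_profile_sigma=self.fiber_profile_sigma,
            fiber_peak=self.fiber_peak,
        )
        if self.background_noise_sd < 0 or self.blob_rate < 0:
            raise ValueError("noise and blob rate must be non-negative")
        nyquist = 0.5 / self.frame_interval
        if self.oscillation_frequency >= nyquist and not self.allow_aliasing:
            raise ValueError(
                f"oscillation_frequency {self.oscillation_frequency} Hz is at or "
                f"above the Nyquist frequency {nyquist} Hz; set allow_aliasing "
                "to render it anyway"
            )

    def amplitude_um(self) -> np.ndarray:
        """Per-column oscillation amplitude in um."""
        x_um = np.arange(self.width_px) * self.pixel_size
        a = self.oscillation_amplitude
        if callable(a):
            amp = np.asarray([a(x) for x in x_um], dtype=float)
        else:
            amp = np.broadcast_to(np.asarray(a, dtype=float), (self.width_px,)).copy()
        if np.any(amp < 0):
            raise ValueError("oscillation amplitude must be non-negative")
        return amp


def _render_fiber_frames(spec: FiberMovieSpec, y_um: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Render Gaussian-ridge frames centered on truth ``y_um`` (T, W)."""
    rows = np.arange(spec.height_px, dtype=float)[:, None]  # (H, 1)
    frames = np.empty((spec.n_frames, spec.height_px, spec.width_px))
    y_px = y_um / spec.pixel_size
    sig2 = 2.0 * spec.fiber_profile_sigma**2
    for t in range(spec.n_frames):
        ridge = spec.fiber_peak * np.exp(-((rows - y_px[t][None, :]) ** 2) / sig2)
        frame = spec.background_level + ridge
        if spec.blob_rate > 0:
            for _ in range(rng.poisson(spec.blob_rate)):
                bx = rng.uniform(0, spec.width_px)
                by = rng.uniform(0, spec.height_px)
                amp = spec.fiber_peak * rng.uniform(0.8, 1.2)
                s2 = 2.0 * spec.blob_sigma_px**2
                frame = frame + amp * np.exp(
                    -((rows - by) ** 2 + (np.arange(spec.width_px)[None, :] - bx) ** 2) / s2
                )
        if spec.background_noise_sd > 0:
            frame = frame + rng.normal(0.0, spec.background_noise_sd, frame.shape)
        frames[t] = np.clip(frame, 0.0, None)
    return frames


def _resting_centerline_um(spec: FiberMovieSpec) -> np.ndarray:
    x_um = np.arange(spec.width_px) * spec.pixel_size
    mid = x_um.mean()
    y0 = 0.5 * spec.height_px * spec.pixel_size
    return y0 + 0.5 * spec.curvature * (x_um - mid) ** 2


def make_fiber_movie(spec: FiberMovieSpec) -> tuple[ImageSequence, np.ndarray]:
    """Render an oscillating-fiber movie.

    Returns the movie and the ground-truth centerline ``y(t, x)`` in um
    (dorsoventral position of the ridge center per frame and column).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    phase = rng.uniform(0, 2 * np.pi) if spec.oscillation_phase is None else spec.oscillation_phase

    t = np.arange(spec.n_frames) * spec.frame_interval
    amp = spec.amplitude_um()                      # (W,)
    base = _resting_centerline_um(spec)            # (W,)
    osc = np.sin(2 * np.pi * spec.oscillation_frequency * t + phase)  # (T,)
    y_um = base[None, :] + amp[None, :] * osc[:, None]

    frames = _render_fiber_frames(spec, y_um, rng)
    seq = ImageSequence(
        frames, pixel_size=spec.pixel_size, frame_interval=spec.frame_interval,
        exposure=spec.frame_interval, meta={"generator": "fiber", "seed": spec.seed},
    )
    return seq, y_um


def retraction_law_um(t_s, D_mm2_s: float, strain: float,
                      prefactor: float = 2.0 / np.sqrt(np.pi)) -> np.ndarray:
    """Free-end retraction X(t) = c sqrt(D t) dL/L, in micrometres.

    ``D`` in mm^2/s, ``t`` in seconds; X returned in um (1 mm = 1000 um).
    """
    t_s = np.asarray(t_s, dtype=float)
    if np.any(t_s < 0):
        raise ValueError("time since ablation must be >= 0")
    return 1000.0 * prefactor * np.sqrt(D_mm2_s * t_s) * strain


@dataclass(frozen=True)
class RetractionMovieSpec:
    """Post-ablation movie: two cut ends receding from the ablation locus."""

    D: float = 5.7                       # mm^2/s, stress diffusion coefficient
    strain: float = 1.0 / 20.0           # dL/L
    prefactor: float = 2.0 / np.sqrt(np.pi)
    ablation_frame: int = 4
    ablation_locus_x: float = 48.0       # um
    noise_sd: float = 0.0                # um jitter on end positions (object space)
    retention_distance: float | None = None  # um; cap on X(t) (stuck end)
    base: FiberMovieSpec = field(default_factory=lambda: FiberMovieSpec(
        n_frames=28, oscillation_amplitude=0.0, curvature=0.0))
    seed: int = 0

    def validate(self) -> None:
        _check_positive(D=self.D)
        if not 0 <= self.strain < 1:
            raise ValueError(f"strain must be in [0, 1), got {self.strain}")
        if not 0 <= self.ablation_frame < self.base.n_frames:
            raise ValueError("ablation_frame must fall within the movie")
        fov = self.base.width_px * self.base.pixel_size
        if not 0 < self.ablation_locus_x < fov:
            raise ValueError("ablation locus outside the field of view")
        if self.strain * self.prefactor == 0 and self.D > 0:
            warnings.warn("strain*prefactor = 0: no visible retraction", stacklevel=2)


def make_retraction_movie(spec: RetractionMovieSpec):
    """Render a cut-fiber movie; returns (movie, ground-truth dict).

    Ground truth carries, per frame from the ablation frame on: time since
    ablation (s) and the noiseless/jittered rostral and caudal end
    positions (um).  Ends that have left the field of view are NaN.
    """
    spec.validate()
    b = spec.base
    b.validate()
    rng = np.random.default_rng(spec.seed)

    fov_um = b.width_px * b.pixel_size
    x_um = np.arange(b.width_px) * b.pixel_size
    base_y = _resting_centerline_um(b)

    n_post = b.n_frames - spec.ablation_frame
    t_post = np.arange(n_post) * b.frame_interval
    X = retraction_law_um(t_post, spec.D, spec.strain, spec.prefactor)
    if spec.retention_distance is not None:
        X = np.minimum(X, spec.retention_distance)
    jit_r = rng.normal(0, spec.noise_sd, n_post) if spec.noise_sd > 0 else np.zeros(n_post)
    jit_c = rng.normal(0, spec.noise_sd, n_post) if spec.noise_sd > 0 else np.zeros(n_post)
    rostral = spec.ablation_locus_x - X + jit_r
    caudal = spec.ablation_locus_x + X + jit_c
    rostral[rostral < 0] = np.nan       # left the field of view
    caudal[caudal > fov_um] = np.nan

    frames = np.empty((b.n_frames, b.height_px, b.width_px))
    rows = np.arange(b.height_px, dtype=float)[:, None]
    sig2 = 2.0 * b.fiber_profile_sigma**2
    y_px = base_y / b.pixel_size
    ridge_full = b.fiber_peak * np.exp(-((rows - y_px[None, :]) ** 2) / sig2)
    for i in range(b.n_frames):
        if i < spec.ablation_frame:
            present = np.ones(b.width_px, bool)
        else:
            k = i - spec.ablation_frame
            present = np.zeros(b.width_px, bool)
            if not np.isnan(rostral[k]):
                present |= x_um <= rostral[k]
            if not np.isnan(caudal[k]):
                present |= x_um >= caudal[k]
        frame = b.background_level + ridge_full * present[None, :]
        if b.background_noise_sd > 0:
            frame = frame + rng.normal(0, b.background_noise_sd, frame.shape)
        frames[i] = np.clip(frame, 0.0, None)

    seq = ImageSequence(
        frames, pixel_size=b.pixel_size, frame_interval=b.frame_interval,
        exposure=b.frame_interval,
        meta={"generator": "retraction", "seed": spec.seed,
              "ablation_frame": spec.ablation_frame,
              "ablation_locus_x": spec.ablation_locus_x},
    )
    truth = {
        "time_s": t_post,
        "rostral_x_um": rostral,
        "caudal_x_um": caudal,
        "ablation_locus_x_um": spec.ablation_locus_x,
        "X_um": X,
        "D_mm2_s": spec.D,
        "strain": spec.strain,
        "prefactor": spec.prefactor,
    }
    return seq, truth


@dataclass(frozen=True)
class CiliumMovieSpec:
    """A single beating cilium: a segment pivoting about its base.

    theta(t) = mean_angle + beat_amplitude * sin(2 pi f t), measured in
    degrees from the horizontal with 0 deg pointing caudal and positive
    angles tilting into the central canal (up from the ventral wall, down
    from the dorsal wall).
    """

    wall: str = "dorsal"                 # {"dorsal", "ventral"}
    base_xy: tuple[float, float] = (5.0, 1.0)  # um (x, distance from wall)
    length: float = 6.0                  # um
    mean_angle: float = 60.0             # deg from horizontal
    beat_amplitude: float = 15.0         # deg
    beat_frequency: float = 11.2         # Hz
    n_frames: int = 1000
    frame_interval: float = DEFAULT_FRAME_INTERVAL_S
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    width_px: int = 64
    height_px: int = 64
    profile_sigma: float = 1.2           # px
    peak: float = 300.0
    background_level: float = 50.0
    background_noise_sd: float = 0.0
    seed: int = 0
    allow_aliasing: bool = False

    def validate(self) -> None:
        if self.wall not in ("dorsal", "ventral"):
            raise ValueError(f"wall must be dorsal or ventral, got {self.wall!r}")
        if self.beat_frequency < 0:
            raise ValueError("beat_frequency must be >= 0")
        _check_positive(length=self.length, n_frames=self.n_frames,
                        frame_interval=self.frame_interval)
        nyquist = 0.5 / self.frame_interval
        if self.beat_frequency >= nyquist and not self.allow_aliasing:
            raise ValueError(
                f"beat_frequency {self.beat_frequency} Hz violates the Nyquist "
                f"limit {nyquist} Hz of the sampling; set allow_aliasing to "
                "render it anyway"
            )


def make_cilium_movie(spec: CiliumMovieSpec):
    """Render a pivoting-segment cilium movie; returns (movie, truth dict)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    t = np.arange(spec.n_frames) * spec.frame_interval
    theta = spec.mean_angle + spec.beat_amplitude * np.sin(
        2 * np.pi * spec.beat_frequency * t)

    # Base in pixel coordinates; "into the canal" is -rows for ventral
    # (cilium points up) and +rows for dorsal (points down).
    h, w = spec.height_px, spec.width_px
    bx = spec.base_xy[0] / spec.pixel_size
    if spec.wall == "ventral":
        by = h - 1 - spec.base_xy[1] / spec.pixel_size
        canal_sign = -1.0
    else:
        by = spec.base_xy[1] / spec.pixel_size
        canal_sign = +1.0

    n_samp = max(8, int(4 * spec.length / spec.pixel_size))
    s = np.linspace(0, spec.length / spec.pixel_size, n_samp)  # px along segment
    rows = np.arange(h, dtype=float)[:, None, None]
    cols = np.arange(w, dtype=float)[None, :, None]
    sig2 = 2.0 * spec.profile_sigma**2

    frames = np.empty((spec.n_frames, h, w))
    for i in range(spec.n_frames):
        th = np.deg2rad(theta[i])
        px = bx + s * np.cos(th)
        py = by + canal_sign * s * np.sin(th)
        d2 = (rows - py[None, None, :]) ** 2 + (cols - px[None, None, :]) ** 2
        frame = spec.background_level + spec.peak * np.exp(-d2 / sig2).max(axis=2)
        if spec.background_noise_sd > 0:
            frame = frame + rng.normal(0, spec.background_noise_sd, frame.shape)
        frames[i] = np.clip(frame, 0.0, None)

    seq = ImageSequence(
        frames, pixel_size=spec.pixel_size, frame_interval=spec.frame_interval,
        exposure=spec.frame_interval,
        meta={"generator": "cilium", "seed": spec.seed, "wall": spec.wall},
    )
    truth = {
        "theta_deg": theta,
        "mean_angle_deg": spec.mean_angle,
        "beat_frequency_hz": spec.beat_frequency,
        "base_px": (bx, by),
        "wall": spec.wall,
    }
    return seq, truth


@dataclass(frozen=True)
class CalciumTraceSpec:
    """dF/F trace: baseline with slow drift, Gaussian noise, smooth events.

    Events are raised-sine transients of ``event_duration`` seconds whose
    peak is ``event_amplitude`` multiples of ``noise_sd`` above baseline.
    An event whose support extends past the end of the trace is rendered
    truncated (for testing the "completed transient" rule) only when
    ``allow_truncated`` is set; otherwise the spec is rejected.
    """

    duration: float = 75.0               # s
    rate: float = 3.45                   # Hz
    baseline_level: float = 1.0          # dF/F units
    noise_sd: float = 0.05
    drift_per_min: float = 0.0           # baseline drift, dF/F per minute
    event_times: tuple[float, ...] = ()  # s, event onsets
    event_amplitude: float = 6.0         # multiples of noise_sd
    event_amplitude_abs: float | None = None  # dF/F; overrides the multiple
    event_duration: float = 3.0          # s
    allow_truncated: bool = False
    seed: int = 0

    def validate(self) -> None:
        _check_positive(duration=self.duration, rate=self.rate,
                        event_duration=self.event_duration)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.event_duration > self.duration:
            raise ValueError("event_duration exceeds the trace duration")
        for t0 in self.event_times:
            if t0 < 0 or t0 >= self.duration:
                raise ValueError(f"event time {t0} outside the recording")
            if t0 + self.event_duration > self.duration and not self.allow_truncated:
                raise ValueError(
                    f"event at {t0} s does not complete before the trace end; "
                    "set allow_truncated to render it"
                )


def make_calcium_traces(spec: CalciumTraceSpec, n_cells: int = 1):
    """Generate ``n_cells`` traces sharing event times, independent noise.

    Returns ``(traces, t_s, truth)`` where traces has shape
    ``(n_cells, n_samples)`` and truth lists each event's onset, peak
    amplitude (dF/F above baseline) and completion flag.
    """
    spec.validate()
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(spec.seed)

    n = int(round(spec.duration * spec.rate))
    t = np.arange(n) / spec.rate
    base = spec.baseline_level + spec.drift_per_min * (t / 60.0)

    kernel = np.zeros(n)
    events = []
    for t0 in spec.event_times:
        amp = (spec.event_amplitude_abs if spec.event_amplitude_abs is not None
               else spec.event_amplitude * spec.noise_sd)
        inside = (t >= t0) & (t <= t0 + spec.event_duration)
        kernel[inside] += amp * np.sin(
            np.pi * (t[inside] - t0) / spec.event_duration) ** 2
        events.append({
            "onset_s": t0,
            "amplitude": amp,
            "completed": t0 + spec.event_duration <= spec.duration,
        })

    clean = base + kernel
    noise = rng.normal(0, spec.noise_sd, (n_cells, n)) if spec.noise_sd > 0 else 0.0
    traces = clean[None, :] + noise
    truth = {"events": events, "baseline": base, "noise_sd": spec.noise_sd}
    return traces, t, truth
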