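# fiberkin

In vivo kinematics and mechanics of the **Reissner fiber** — the
acellular SCO-spondin thread (~100 nm radius) running along the midline
of the spinal central canal of larval zebrafish, bathed in
cerebrospinal fluid.  The package is written for researchers analysing
high-speed (40 Hz) sagittal-plane fluorescence movies of the fiber, the
motile monocilia lining the canal, and the calcium activity of
CSF-contacting neurons (CSF-cNs), and for anyone who wants a fully
testable, synthetic-data-backed reimplementation of that analysis.

It provides:

* **Sub-pixel fiber tracking** — a six-step algorithm (global histogram
  background model, anisotropic Gaussian smoothing, per-column argmax
  with clamped parabolic refinement, half-max width validity, iterated
  normalized-convolution smoothing/extrapolation, consistency
  rejection) estimating the curve x → y(x) on every frame to well below
  0.1 px.
* **Motion statistics** — dorsoventral displacement from the temporal
  mean in 2-um rostrocaudal bins (nm), region/group comparisons
  (t-test, Tukey HSD), and spatial PCA with frames as observations.
* **Retraction kinematics** after focal laser ablation — cut-end
  detection, instantaneous and windowed speeds, √t regression,
  fast/slow classification, elongation ΔL from retention positions.
* **Elastic mechanics.**  Modelling the fiber as a taut slender rod,
  the pulling force is F_p = π r_f² E ΔL/L, and a cut end relaxes by
  stress diffusion, x² ~ D t with

      D = π r_f² E / η = r_f² / τ,      X(t) = c √(D t) · ΔL/L,

  giving the relaxation time τ, rupture time T = L²/D, Young modulus
  E = D η / (π r_f²) and rostrocaudal tension profiles under flow or
  cilia forcing.
* **Cilia and calcium analysis** — principal-axis orientation of masked
  cilia with wall-specific angle conventions, beat frequency by
  oscillation counting (spectral cross-check, Nyquist/aliasing flags),
  deterministic two-cluster k-means over image patches, Fisher-exact
  orientation-vs-fiber association, and ΔF/F transient detection
  (running-percentile baseline, 3-SD threshold, completed-event rule).
* **Seeded synthetic generators** for all of the above with exact
  ground truth, so every stage is tested by round trip without any
  real recording.

## Worked example

```python
import numpy as np
from fiberkin import synth, tracking, motion, mechanics as mech

# A 10 s, 40 Hz synthetic movie: 125 nm dorsoventral oscillation.
spec = synth.FiberMovieSpec(n_frames=400, width_px=300, seed=7)
seq, truth = synth.make_fiber_movie(spec)

trace = tracking.track_sequence(seq)
rms = np.sqrt(np.nanmean((trace.y - truth / spec.pixel_size) ** 2))
table = motion.bin_and_displace(trace)
print(f"RMS error vs truth {rms:.3f} px")
print(f"median displacement {np.nanmedian(table.displacement_nm):.1f} nm")

# Mechanics from a fast-retraction slope of 0.161 mm/sqrt(s) at strain 1/20.
D = mech.diffusion_from_slope(0.161e-3, strain=1 / 20, c=1.35)
rep = mech.MechanicalParameters(D=D, L=1e-3, delta_L=0.05e-3).completed().report()
print(f"D = {rep['D_mm2_per_s']:.2f} mm^2/s, tau = {rep['tau_ns']:.2f} ns, "
      f"T_rup = {rep['T_rup_ms']:.0f} ms, E = {rep['E_Pa']:.2e} Pa")
```

prints

```
RMS error vs truth 0.009 px
median displacement 88.7 nm
D = 5.69 mm^2/s, tau = 1.76 ns, T_rup = 176 ms, E = 1.81e+05 Pa
```

The tracker recovers the rendered centerline to ~0.01 px; the median
displacement matches the closed form A/√2 = 88.4 nm for a 125 nm
sinusoid; and a fast-retraction √t slope of 0.161 mm/√s at strain 1/20
yields a stress diffusion coefficient of ~5.7 mm²/s, a nanosecond-scale
material relaxation time, a ~200 ms full retraction time for a 1 mm
fiber, and a rubber-like modulus of order 10⁵–10⁶ Pa.

A command-line front end covers the same stages on TIFF movies:

```
fiberkin simulate fiber --seed 1 --out runs/demo
fiberkin track runs/demo/fiber.tif --out runs/demo
fiberkin displace runs/demo/fiber.tif --out runs/demo
fiberkin mechanics --slope 0.161 --strain 0.05 --out runs/demo
```

## Layout

```
src/fiberkin/
  io.py         calibrated ImageSequence, TIFF + JSON sidecar I/O
  synth.py      seeded generators (fiber, retraction, cilium, calcium)
  tracking.py   six-step sub-pixel centerline tracker
  motion.py     binned displacement statistics, Tukey/t-tests, PCA
  retraction.py cut-end detection, speeds, sqrt-time fits, dL
  mechanics.py  stress-diffusion model and derived quantities
  cilia.py      orientation, beat frequency, k-means, Fisher tests
  calcium.py    baseline, transient detection, activity summaries
  pipeline.py   run configuration, provenance, stage ordering
  cli.py        click front end (`fiberkin`)
```

See `docs/methods.md` for the model assumptions, parameter defaults,
numerical choices and known limitations.
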