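# Methods

## Scope and data model

`fiberkin` analyses sagittal-plane fluorescence movies of the central
canal of larval zebrafish: the Reissner fiber (an acellular SCO-spondin
thread, radius ~100 nm, well below the diffraction limit), the motile
monocilia that line the canal walls, and calcium activity of
CSF-contacting neurons.  A movie is a `(frames, rows, cols)` array with
pixel size (um/px) and frame interval (s) attached; rows increase
ventrally, columns increase caudally.  Real recordings never embed
their calibration in a standard place, so pixel size and frame interval
are required configuration, not constants — the package defaults to
0.1625 um/px (typical 40x camera sampling) and 40 Hz only in its
synthetic generators.

## Fiber tracking

The tracker estimates a smooth sub-pixel curve x -> y(x) per frame in
six steps: (1) a global background model from the whole-sequence
intensity histogram — mode I0, mean-below-mode I1, deviation
dev = I0 - I1 — subtracting I0 + dev and clipping at zero; (2)
anisotropic Gaussian pre-smoothing (sigma_x = 3.5 px along the fiber,
sigma_y = 1.9 px across it; reflective boundaries); (3) per-column
integer argmax with a clamped three-point parabolic refinement
(offset = (I+ - I-)/(4 I0 - 2 I- - 2 I+), clamped to [-1, 1]; a
degenerate denominator keeps offset 0; argmax ties take the smallest
row); (4) per-column half-max width, with columns of width >= 10 px
invalid — a bright cell overlapping the column inflates the width and
removes it from the valid domain; (5) iterated normalized-convolution
smoothing y := (y*G)/(1*G) with sigma = 5.8 px, resetting y to the raw
estimates on the valid domain each pass; the (1*G) division corrects
image-edge attenuation and the iteration extrapolates across invalid
columns; (6) columns whose raw estimate departs from the smooth curve
by more than 1 px are dropped and step 5 re-runs for the final curve.

Numerical choices: step 5 stops at a sup-norm update below 1e-6 px or
100 iterations, whichever comes first (the iteration is a contraction,
so both are safe); the mode in step 1 is taken over integer-quantized
intensities, matching camera counts.  The pre-smoothing sigmas, the
smoothing kernel, the width limit and the consistency tolerance are all
configurable `TrackerParams`.

Why a parabolic refinement works here: after step-2 smoothing the ridge
cross-section has an effective sigma of ~2.4 px, and the three-point
parabola's bias on such a profile is below 0.01 px; on noiseless
synthetic ridges the full pipeline recovers the centerline to
< 0.01 px RMS, and < 0.1 px at peak signal-to-noise 5.

## Displacement statistics and motion PCA

The tracked curve is discretized in 2-um bins along the rostrocaudal
axis; per bin and frame, the displacement is the absolute deviation of
the bin-mean position from its temporal mean, in nm.  For a pure
sinusoidal oscillation of amplitude A with uniformly covered phase the
median displacement is A/sqrt(2) (median of |A sin|).  Group summaries
report median +/- SD at two granularities — pooled bin-frame values and
per-fish medians — because the natural observation unit on real data is
ambiguous; two groups are compared with an unpaired two-tailed t-test
and three or more with Tukey's HSD (statsmodels).  The package operates
on the full trace rather than cropping the field of view into segments
and concatenating: per-bin temporal means are identical either way.

Motion PCA treats each frame as one observation over all pixels,
mean-centers over time and takes an exact SVD (no whitening).
Components are orthonormal images defined up to sign (tests compare
|cosine|); fractions are percent of total temporal variance.  A rigid
dorsoventral translation of a ridge produces a first component with
opposite-sign lobes on the two fiber edges — the translation signature.

## Retraction kinematics

After a focal cut the two fiber ends recede from the ablation locus.
Ends are located per frame as the extreme column (toward the gap) whose
background-subtracted ridge signal exceeds half the pre-cut ridge
intensity, refined by linear interpolation of the crossing; an end that
leaves the field of view is censored, never extrapolated.  Instantaneous
speed is |dx|/exposure with a 25 ms default exposure.  The first 50 ms
after the cut carry laser artifacts and are excluded from all fits and
speed windows; the "initial speed" is the distance accrued between 50
and 75 ms divided by 25 ms, and the maximum speed is over instantaneous
speeds after the artifact window.

Retraction distance regressed on sqrt(time) gives the slope
alpha = c sqrt(D) (dL/L).  Fibers are grouped fast/slow by the
deterministic two-cluster k-means on log(alpha) — the log scale
reflects the order-of-magnitude separation between the two regimes, and
the grouping rule is configurable since no canonical rule exists.
Retention (an end stopping inside the field of view) is declared when
the instantaneous speed stays below 2 um/s for 10 consecutive frames —
a rule chosen to be robust at 40 Hz with sub-um jitter — and the
elongation dL is the distance from the retention position to the
ablation locus; without retention dL is only lower-bounded by the field
half-width and is reported as a censored bound.

## Elastic mechanics

The fiber is a slender elastic rod under tension in a viscous fluid.
Pulling force F_p = pi r_f^2 E (dL/L); balancing it against the viscous
drag on the relaxing end gives a stress-diffusion law x^2 ~ D t with
D = pi r_f^2 E / eta = r_f^2 / tau.  The observable free-end retraction
is X(t) = c sqrt(D t) (dL/L).  The prefactor c defaults to
2/sqrt(pi) ~= 1.13 (the standard 1-D diffusion-front constant with the
slender-body drag logarithm folded in) but is configurable and echoed
in every output: back-solving published fast/slow slope-strain pairs
implies an effective c of ~1.33-1.35, and the package deliberately does
not hard-code either reading.  An exact-log drag form
(2 pi / ln(L/r_f)) is available for sensitivity analysis.

Derived quantities: tau = r_f^2 / D (2 ns for r_f = 100 nm and
D = 5 mm^2/s), rupture time T = L^2/D = tau (L/r_f)^2 (200 ms at
L = 1 mm), Young modulus E = D eta / (pi r_f^2) (~1.6e5 Pa for
water-like eta = 1e-3 Pa s; an order-of-magnitude estimate since eta of
CSF is uncertain).  Tension profiles along the fiber: under
rostral-to-caudal flow at speed U, strain(l) = U l / D (0.6% maximum
for U = 10 um/s, L = 3 mm, D = 5 mm^2/s — an order below the rostral
1/20 strain, i.e. flow alone under-predicts rostral tension); under
distributed cilia forcing, F_p(l) = nu f_p l with nu the linear link
density.  The fiber length L enters only as an explicit argument — it
is used at ~3 mm for strain estimates and 1 mm for the rupture-time
estimate, and the code never assumes one value.  All internal
computation is SI; reporting units (mm^2/s, um/s, ns, ms, Pa) appear
only at interfaces.

## Cilia analysis

Orientation: the temporal-mean image inside a user mask isolating one
cilium is thresholded at half its maximum; the blob must be one
connected component, and its intensity-weighted principal axis is
oriented into the canal and expressed in degrees from the horizontal
with 0 deg pointing caudal (ventral wall: signed -90..+90, positive =
caudal tilt; dorsal wall: folded 0..90).  Beat frequency: the
fluorescence trace in an ROI covering a motile section is linearly
detrended and upward mean crossings counted per second; a periodogram
peak is reported alongside as an audit, and estimates at the 20 Hz
Nyquist ceiling of 40 Hz recordings carry an aliasing flag.  The ROI
matters at this sampling rate: `sweep_mask` builds the half-sweep
region above the mean beat angle, inside which the cilium dwells for
half of each cycle, giving a smooth once-per-cycle signal; a tiny tip
ROI is occupied too briefly per cycle to count reliably at ~3 samples
per beat.  Polarity is per cilium: 'z-plane' when flagged as beating
out of the imaging plane, 'dorsal' within a configurable 10 deg of the
vertical, otherwise 'caudal'.

The two-cluster k-means used to dichotomize image patches (fiber
up/down) initializes its centers with the first two patches and
iterates assignment/update until the labels stabilize, so it is
deterministic given the input order; duplicate initial centers fall
back to the farthest patch.  Orientation-vs-fiber association
dichotomizes per-frame orientations at the per-cilium median and tests
the 2x2 table with Fisher's exact test (two-sided).

## Calcium analysis

The baseline of a dF/F trace is a running 20th percentile over an 8 s
window, plus the Gaussian quantile offset (+0.8416 sigma) so that it
estimates the resting level rather than its lower tail; the noise SD is
the scaled MAD of the residual about a running median.  Events must
exceed baseline + 3 SD for at least two consecutive samples and extend,
with hysteresis, until the trace returns below baseline + 1 SD; only
events whose onset and return both lie inside the recording are counted
(the "completed transient" rule), so a transient still above threshold
at the last sample is discarded.  With these defaults the
false-positive rate on pure Gaussian noise is ~2% per 75 s trace and
the sensitivity for 5-SD completed events exceeds 95%.  A cell is
active if it has at least one event; activity summaries report percent
active, events/min among active cells and the after/before active-cell
ratio per fish, with paired two-tailed t-tests across fish.

## Synthetic data: what it emulates and what it does not

The generators render (i) a Gaussian-profile ridge (sigma 1.5 px,
PSF-limited) over Gaussian background noise with optional bright 2-D
Gaussian blobs of fiber-comparable intensity, oscillating dorsoventrally
with an amplitude profile that may be graded along the body axis
(defaults: 125 nm amplitude, 7.3 Hz — below the 20 Hz Nyquist limit of
40 Hz sampling; real oscillation frequencies are unresolved at this
sampling rate); (ii) cut-fiber movies whose ends follow
X(t) = c sqrt(D t) (dL/L) exactly, with object-space (um) jitter so
tolerances are calibration-independent, optional retention capping, and
defaults matching the fast-retraction regime (D = 5.7 mm^2/s,
dL/L = 1/20); (iii) beating cilia as rigid segments pivoting about an
anchored base (default 11.2 Hz); (iv) dF/F traces with drift, Gaussian
noise and raised-sine transients (75 s at 3.45 Hz by default).

Not emulated: diffraction and depth-dependent PSF, photobleaching,
camera gain/shot-noise statistics, fiber flexural dynamics (the
synthetic fiber translates rigidly per column), 3-D ciliary waveforms,
and motion artifacts from muscle twitches.  Passing round-trip tests
therefore demonstrates the correctness of the estimators under the
stated image model, not robustness to every nuisance of real
recordings; the tracker's absolute displacement medians on real data
(tens of nm) additionally depend on imaging noise floors that the
fixed-larva condition is needed to calibrate.

## Problem sizes in the test suite

The suite verifies tracker recovery on 100-frame, 600-column movies,
the displacement median on a 1000-frame movie, slope recovery over 200
seeded jitter realizations, the k-means oracle by exhaustive
enumeration up to 12 patches, and detection rates on 1000 synthetic
traces; the whole suite runs in well under a minute on one CPU.

## Known limitations

Single-fiber tracking only; frames where the fiber leaves focus are
flagged untracked rather than bridged.  Retraction analysis assumes the
movie was pre-rotated so the fiber is horizontal.  The ablation frame
and locus are inputs, not detected.  ROI/mask selection for cilia and
calcium is manual.  The retraction-law prefactor is a modelling
constant, not a measured one, and every derived D scales with c^-2.
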