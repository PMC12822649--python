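# Methods

This note documents the models, conventions and numerical choices
behind `foveloc`, in the spirit of a methods section: what each stage
assumes, which parameters matter, and what the synthetic test bed does
and does not establish about behaviour on real donor imagery.

## Coordinate conventions

Pixels are 0-based `(row, col)`. Physical coordinates are millimetres
in the en-face plane, `x` along columns, `y` along rows, origin at the
reference marker — the small retinal impression whose imaged location
registers the punch axis against the imaging axis. B-scan acquisition
order maps to increasing fundus row (an inferior→superior raster; the
direction is a convention, not a measurement). Detection boxes are
half-open pixel intervals. Pixel-centre mapping rounds half-up; motor
steps round half away from zero; the centre pixel of an even span and
the central image of an even run both take the lower middle.

Sign convention, used consistently: a positive commanded step on an
axis moves the *observed* fovea in the negative direction of that axis
(the stage carries the sample under a fixed optical/punch axis), so the
command that cancels an observed offset `o` is `round(o · steps_per_mm)`
per axis.

## Synthetic scenes

The generator emulates a Spectralis-style raster of an ex vivo eyecup.
Defaults: 61 B-scans of 196×256 px at 12.5 µm/px laterally and
5.5 µm/px axially, spaced 0.1 mm; a 288×384 px fundus image at
25 µm/px; a five-layer retina (total thickness 0.38 mm) whose
brightnesses alternate the way inner retina / plexiform layers do; a
foveal pit of depth 0.10 mm and full width at half depth 0.8 mm. The
raster therefore spans ±3 mm vertically and ±1.6 mm horizontally around
the scan centre, and a default pit crosses 9 scan lines — values chosen
to look like a macula-centred volume scan of a human posterior pole.

The pit is a 2-D Gaussian depression parameterized by its full width at
half depth. It is rendered as *inner-layer thinning*: the inner surface
dips while deeper layer boundaries stay fixed, which is what a real
foveal pit looks like in cross-section (and which, unlike a rigid
downward shift of all layers, changes the image mean so that shallow
image statistics can verify class separability of generated training
sets). A B-scan is ground-truth positive when its scan line passes
within half the pit width of the fovea centre, i.e. where the
depression is at least half its maximum; this makes the positive set a
single contiguous run by construction.

Noise is additive Gaussian on the rendered intensities, a deliberate
single-dial simplification: it lets the signal-to-noise ratio be swept
in classifier and scan-line stress tests, but it does not reproduce the
multiplicative, spatially correlated speckle of real OCT, nor motion,
vignetting, or pathology. Passing tests on these scenes therefore
demonstrate the correctness of the pipeline's logic, geometry and
calibration — not clinical-grade robustness of the classifier or
detector, which on real data come from training on real donor images.

Scene generation is bit-deterministic in (parameters, seed). The fovea
may be placed outside the scan raster (the truth then lists no positive
B-scan), which is how the pipeline's no-fovea abort path is exercised.

## Baseline pit detector

The inner retinal surface is extracted per column as the first row
brighter than the midpoint of the image intensity range, gaps filled by
nearest-neighbour interpolation, then median-smoothed over 7 columns.
The retinal baseline is a degree-2 polynomial fitted by asymmetric
least squares: residuals more than half a pixel *above* the running fit
(i.e. toward deeper rows — candidate pit) are downweighted by 0.03, and
the fit is iterated to a fixed point (≤ 20 iterations). This drives the
polynomial onto the un-dipped lower envelope even when the pit drags a
plain fit down.

The deepest depression must reach `min_pit_depth_px` (default 6 px) to
count. Among equal-depth pits (within half a pixel) the earliest
contiguous group wins. The reported centre is the midpoint of the pit
bottom plateau measured on the *raw* surface profile — a quantity
immune to residual tilt of the fitted baseline — and the box columns
span the half-depth width laid out symmetrically about that centre; a
pit clipped by the image border therefore keeps an unbiased centre but
may report a truncated width. Confidence is depth as a fraction of
image height; it orders detections within this backend and is not
comparable to a learned model's score.

The learned single-stage detector of the original workflow (trained on
292 annotated foveal images, validated on 39, 30 epochs) is supported
as an optional pluggable backend with the same contract, including the
normalized `class cx cy w h` annotation dialect; it needs the optional
`ultralytics` dependency and externally downloaded weights/data, so the
deterministic baseline is the supported offline path and the reference
oracle in tests.

## Scan-line geometry

The green overlay is isolated in HSV space (hue 90°–150°, saturation
≥ 0.4, value ≥ 0.3 — thresholds chosen to pass the rendered overlay and
reject the reddish fundus background with wide margins), edges are
extracted with a Canny filter, and a Hough line transform restricted to
±5° of horizontal finds the line; ties in accumulator support resolve
to the smallest row. The winning row is refined by the centroid of
masked pixels within ±3 rows, which makes the result exact on noiseless
renderings (the renderer draws the stripe symmetrically, shrinking it
at image borders rather than clipping it one-sided). Under additive
noise up to 10 % of the line contrast the detected row stays within one
row of truth (seeded test).

The scan-line pixel span corresponds 1:1 to the B-scan's columns; the
column map is linear with half-up rounding, monotone and endpoint-exact.

## Stage calibration and targeting

Calibration probes each axis independently (default 400 steps, moved
and moved back per repeat), estimating steps-per-mm as
`|probe| / mean |observed displacement|`; the repeat scatter is
reported as a residual SD. No cross-axis coupling is modelled — the
simulated stage has none, and the physical gantry's axes are nominally
orthogonal. With observation noise of 0.01 mm and 25 repeats the
estimate lands within 2 % of truth (seeded tests over 40/80/160
steps/mm); noiseless it is exact. Closed-loop positioning repeats
observe → plan → move until the command rounds to zero, converging to
within one motor step (the quantization bound) on a noiseless stage and
to the observation-noise floor otherwise; averaging a few observations
per iteration (default 3) keeps noisy loops contracting.

Residual offsets are summarized as mean ± sample SD (n−1) of Euclidean
magnitudes; a single trial reports SD 0 with an explicit
`sd_defined=False` flag.

## Classifier recipe

Architecture (fixed, audited by an introspection test): conv 3×3 ×32 →
pool → ×64 → pool → ×128 → pool → ×256 → pool → flatten → dense 512 →
dense 256 → sigmoid(1), ReLU throughout, 'same' convolution padding so
each block halves the spatial size exactly (a 256×256×3 input flattens
to 16×16×256, giving 34 074 945 trainable parameters, verified against
a closed-form hand count). Training: batch 12, 30 epochs, Adam at
1e-3, binary cross-entropy, stratified 70/15/15 train/validation/test
split, online augmentation (brightness ±0.2 additive, contrast and
saturation factors 0.8–1.2, hue shift ±0.05 of the circle; grayscale
B-scans are replicated to three channels so the chromatic augmentations
are defined), and the checkpoint of the highest-validation-accuracy
epoch is retained (earliest on ties). The decision threshold is 0.5,
overridable in the open interval (0, 1).

The engine (`foveloc.nn`) implements these layers directly on numpy,
lowering convolutions to BLAS matrix products via im2col; float32
throughout, He-normal initialization from a seeded generator, so a
fixed seed reproduces training bit-for-bit. Backpropagation is verified
against central-difference gradients (tolerance 5 %, the float32
differencing noise floor).

The classifier experiments train on a 60-image balanced synthetic set
(pit position, width and depth randomized; noise SD 0.02) resized to
64×64 — a resize target is a free preprocessing choice, and 64×64 keeps
the full 30-epoch recipe under a minute on one CPU while leaving all
four pooling stages meaningful; the package default remains 256×256.
The set is verified linearly separable by a plain pixel-mean threshold
before any training, so the expected held-out accuracy is 1.0, and the
recipe achieves it at the documented fixed seed (generator seed 11,
training seed 1 — fixed because a train/val/test split of 60 images is
itself part of the experimental condition; across arbitrary seeds the
9-image test split occasionally yields 8/9). This is a scaled-down
analogue of training on the 78 donor images, which are an external
download and not required for build or test.

## Pipeline and determinism

The acquisition trigger is a file-readiness watcher: a store directory
with a manifest is polled until every listed file exists, so partial
stacks are never ingested; image ids continue after a persistent
per-store maximum, so re-runs never reuse identifiers. One seed in the
pipeline config drives scene generation, stage noise and any sampling;
run reports contain no timestamps, and two runs with the same config
are byte-identical. Any stage failure aborts the run with the stage
name and cause recorded — no move command is ever emitted after an
error.

End-to-end accuracy bookkeeping: along `x` the limiting quantum is the
fundus pixel (25 µm); along `y` it is the B-scan spacing (0.1 mm), four
times coarser. The geometry acceptance scenes therefore place the
fovea's `y` exactly on a (randomly chosen) scan line while `x` stays
continuous-random — this isolates the geometric chain, whose error must
stay within one fundus pixel per axis, from the irreducible ±half-
spacing `y` sampling error that any raster acquisition has. A separate
property covers the unsnapped case at the spacing/2 bound.

## Known limitations

* The synthetic retina is flat with Gaussian noise; no speckle
  statistics, curvature, vessels, shadowing or pathology. Classifier
  and detector performance on these scenes upper-bounds nothing about
  real donor data.
* The baseline detector assumes a single dominant pit on a slowly
  varying (degree ≤ 2) surface; multiple comparable depressions or
  strong curvature would need the learned backend.
* The simulated stage is ideal apart from observation noise: no
  backlash, drift or axis coupling. Calibration accuracy on hardware is
  bounded by the physical validation protocol (reference-marker offset
  compensation), not by this software.
* Optical distortion of the adapter lens is not corrected in software;
  the reference-marker protocol absorbs it physically.
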