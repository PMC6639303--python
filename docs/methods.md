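# Methods

`pmrkit` quantifies five live-cell assays of plasma-membrane repair (PMR)
and its calcium-handling machinery: FM-dye entry after focal laser injury,
Fluo-4 cytosolic Ca²⁺ transients, injury-triggered ER fragmentation, FRAP
of ER-membrane proteins, and the dual-dextran glass-bead injury assay.
Because the assays it targets are defined by their measurement procedures
rather than by any public dataset, the package ships a synthetic-data
module that emulates each assay with machine-readable ground truth; every
analysis stage is validated against that ground truth.  This note records
the models, the parameters that matter, and the design choices made where
the procedures leave latitude.

## Data model and conventions

Stacks are `T×C×Y×X` arrays with a frame interval in seconds; coordinates
are 0-based, pixel-centred, `(row, col)` everywhere.  ROIs (cell outline,
injury point, background region, bleach region) are inputs, matching the
per-cell workflow of laser-injury experiments — the package deliberately
does not auto-segment single injured cells.  Kinetic traces put time zero
at the injury (or bleach) frame.  ΔF/F is `(F − F₀)/F₀` with `F₀` the mean
over a baseline window; the default window is every frame strictly before
the injury frame (at least two required), since acquisitions routinely
include pre-injury frames but no convention fixes the window length.
Background subtraction (mean of a cell-free ROI, per frame) is optional and
recorded in the trace metadata, because whether published ΔF/F traces were
background-corrected is generally unstated; both modes are first-class.

## Synthetic assay models

The generators draw the *study conditions*; their defaults are fixed once
and all tests and the acceptance script run at them.

* **Dye influx** — piecewise linear: baseline 100 AU, entry at
  `influx_rate` (default 2 AU/s) from the injury frame, hard plateau at
  `repair_time` for repairing cells, unbounded rise clipped at the
  detector's dynamic range for non-repairing cells.  Default acquisition: 2
  s frame interval, 90 frames, injury at frame 5, matching the cadence of
  FM-dye laser-injury recordings.  This is the simplest shape that
  reproduces the qualitative repairing/non-repairing trace families.
* **Calcium transient** — baseline + A·(exp(−t/τ_d) − exp(−t/τ_r)),
  renormalised so the peak equals the requested amplitude; τ_r = 0 is the
  instant-rise limit and τ_r = τ_d degenerates smoothly to the alpha
  function t·e^(1−t/τ).  Default sampling 5 frames/s for ~3 min, the
  regime of Fluo-4 injury recordings.
* **ER field** — a two-channel image of an elliptical cell.  Tubular ER is
  sinusoidal ridges (spacing 8 px) running parallel to the injury axis;
  punctate ("bead-on-string") ER is Gaussian spots (σ 1.5 px) on the ridge
  skeleton with gaps.  The punctate region is exactly the portion of the
  injury axis nearest the injury point with length `fraction × axis
  length`; the generator emits the per-pixel punctate label mask as ground
  truth rather than re-measuring its own pixels.
* **Bead field** — non-overlapping disk cells placed by rejection
  sampling; exactly `n_injured` carry the green (injury) label and exactly
  `n_failed ⊆ injured` also carry red.  Defaults: 150 cells in 512²,
  radii 8–13 px.
* **FRAP** — pre-bleach plateau, instantaneous bleach by `bleach_depth`,
  mono-exponential recovery of `mobile_fraction` of the depth; an optional
  multiplicative exp(−t/τ_acq) emulates acquisition bleaching for testing
  reference correction.

Noise is a standard camera model: Poisson shot noise at a configurable
AU/photon scale plus additive Gaussian read noise (defaults: shot noise
off, read noise 5 AU on a 12-bit range — neither the bit depth nor the
camera noise of the source acquisitions is documented, so these live in
config, not code).  Trace-level generators use Gaussian noise of 2 AU on a
100 AU baseline, the read noise left after averaging a typical ROI.  With
all noise at zero every pixel equals its analytic model exactly, and
identical spec + seed gives bit-identical output.

What the generators do **not** emulate: diffusion physics of dye or Ca²⁺,
optics (no PSF beyond the Gaussian spots), cell motion, focus drift,
heterogeneous expression, or overlapping cells.  Passing tests therefore
demonstrate that the estimators are correct and unbiased *given* the
stated signal models and noise — not that they are robust to every
pathology of real microscopy data.

## Analysis procedures

**Repair classification.**  A cell is repaired when the slope of its
smoothed ΔF/F trace stays below `slope_epsilon` (0.005 ΔF/F·s⁻¹)
throughout a sliding window of 20 s starting no later than 120 s
post-injury; the first such window start is the plateau time.  The verbal
criteria being operationalised are "repairs within about a minute" vs
"entry continues beyond two minutes", so the horizon sits between them and
everything is configurable and echoed in the output.  Smoothing is
Gaussian with σ = 1 frame: the plateau-onset estimate lags the true repair
time by ≈0.67·σ_t, so σ of one frame keeps the bias below one frame
interval while still suppressing read noise (at the default SNR the
classifier is ≥95 % accurate over hundreds of cells, and exact without
noise).  A plateau caused by detector saturation (raw maximum at the
ceiling) is flagged `saturated`, not `repaired`.

**Calcium metrics.**  Peak and threshold crossings are read from a
σ = 2-frame Gaussian-smoothed copy of the trace; the AUC integrates the
raw trace (trapezoid) from injury to 180 s, with negative excursions
clipped at zero by default (togglable — whether published AUCs clipped is
unstated).  The peak is localised to sub-frame precision by a quadratic
fit through the three samples around the smoothed maximum; without this
the ±dt/2 peak-time quantisation pushes the clearance-75 error past one
frame interval for some decay constants.  Clearance-75 is the linearly
interpolated first post-peak time at which the smoothed trace falls to
25 % of peak — for a pure exponential decay this equals τ·ln 4, the
identity the tests check.  Traces whose signal never reaches 25 % of peak
within the recording are flagged right-censored and excluded from cohort
means (with a censored count); all-zero traces are flagged `no-transient`.

**ER fragmentation.**  The injury axis is the straight segment from the
injury point to the boundary point of the cell polygon at maximal
Euclidean distance (near-ties broken toward the polygon's principal axis).
Each point along the axis is scored by the spatial coefficient of
variation of the band-averaged intensity profile in a window (16 px long,
band ±12 px) around it: tubules parallel to the axis give a flat profile,
puncta an oscillating one.  Only in-mask band samples enter the profile,
so the cell edge cannot masquerade as texture; windows with under 50 %
mask coverage are flagged and imputed from the nearest valid window.  The
fragmented length is the contiguous run of above-threshold windows from
the injury point (isolated distal punctate windows are counted
separately), and the decision threshold is calibrated, not hand-set: pure
tubular and pure punctate fields are generated at matched texture and
noise parameters and the threshold is the *quadrature* midpoint
√((s_tub² + s_punc²)/2) of their mean scores.  Window variance mixes
linearly across the texture boundary, so a window straddling it halfway
scores at exactly this value — the arithmetic midpoint, by contrast,
systematically overshoots the front by ~4 % of the axis.  Measured
recovery error is ≤0.013 in fraction at the defaults.  Whether published
fragmented lengths were read off one frame or the maximum over time is
unspecified; scoring takes an explicit frame, with a per-frame time-course
operator (no temporal smoothing) alongside.

**FRAP.**  Traces are scaled so the pre-bleach mean is 1; an optional
whole-cell reference divides out acquisition bleaching (both modes
recorded — published recovery curves rarely state which was used).
Recovery is fitted by least squares to y₀ + M·(1 − e^(−t/τ)) over
post-bleach points with y₀, M, τ all free; the mobile fraction is
M/(1 − y₀).  Initialising y₀ from the mean of the first two post-bleach
frames is noise-robust, and leaving it free lets the noise-free fit
recover the floor exactly.  A fitted mobile fraction outside [0, 1.05] is
flagged implausible rather than clipped.  A two-exponential variant (AIC
reported) exists for curvature checks; the mono-exponential is the default
because the comparisons it supports are of whole recovery curves, not
diffusion-model parameters (spot geometry is not modelled).

**Bead counting.**  Cells are connected components (≥30 px) of the
Otsu-thresholded pixelwise-maximum of the two channels; a cell is positive
for a channel when its mean intensity exceeds the channel's Otsu
threshold, floored at background mean + 3 SD so a channel with no genuine
foreground (e.g. a red channel in a fully repairing field) yields no
positives.  The rule replaces by-eye positivity with something symmetric
in the channels and validated to exact counts on noise-free fields.
Red-only detections are reported as anomalies, never as injuries.
Touching-cell watershed splitting exists behind a flag for real data; the
validated path keeps cells disjoint.

**Statistics.**  Two-group comparisons only (the assays are pairwise by
design): Shapiro–Wilk per sample plus median-centred Levene at α = 0.05
select between unpaired Student's t and Mann–Whitney; tests are two-sided;
the chosen test is recorded.  Mann–Whitney uses the exact null
distribution when both n ≤ 8 without ties (matching a brute-force
enumeration oracle in the tests) and the tie-corrected normal
approximation otherwise.  Identical constant samples return p = 1 with a
zero-variance warning.  No multiple-testing correction by default; Holm is
available.

## Numerical choices and degenerate inputs

* Baseline F₀ ≤ 0 aborts ΔF/F with a message pointing at background
  subtraction rather than silently producing infinities.
* Downsampling is block-mean with times at block centres; a trailing
  partial block is dropped.
* Curve fits run with parameter bounds (mobile amplitude ≥ 0, τ > 0) and
  report non-convergence with the initialisation values.
* Bead-field packing failures raise after bounded retries, naming the
  constraint; degenerate ellipse geometries (semi-axis < 2 px) and
  indistinguishable ER textures (spacing < 2 × spot σ) are rejected at
  construction.

## Problem sizes used in validation

The test suite and the acceptance script validate at: 100 noise-free and
200 noisy cells for repair classification; four decay constants (5–40 s)
for clearance-75; 20 stacks per fraction ∈ {0, 0.25, 0.5, 0.75, 1} and
noise level for ER recovery; 100 noisy FRAP replicates; 50 randomized bead
specs plus 200 replicate fields at a 35 % failure probability; 1000
null replicates for the type-I error of the auto-selected test.  These
sizes give Monte-Carlo error comfortably below each tolerance while
keeping the whole validation run to a few minutes on one core.

## Known limitations

ROIs must be supplied; the fragmentation score assumes the cell is
stationary across the scored frames and that tubules run roughly parallel
to the injury axis at the band scale; FRAP fitting is empirical
(exponential), not a diffusion model; bead counting assumes registered
channels and, by default, non-touching cells; no proprietary microscope
formats are read (TIFF + JSON only); physical units are reported only when
a pixel size is provided.
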