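# Methods

## Scope and shape

`catflux` is organised as an analysis project: the library under
`src/catflux/` holds every computation, the numbered scripts under
`analysis/` are thin narrative drivers, and `scripts/acceptance.py`
recomputes the headline quantities end-to-end.  The package covers two
linked workflows: (i) a perturbation study of calcium handling in a
minimal hiPSC-cardiomyocyte model, and (ii) the fluorescence-imaging
analytics used around genetically encoded sensors.  A seeded generator
(`synth.py`) produces every input class with embedded ground truth.

## Minimal calcium-handling model (`model.py`)

### Structure

Two well-mixed Ca²⁺ pools — cytosol `c` (µM) and sarcoplasmic reticulum
`s` (µM, an abstract small fast pool, not a literal SR volume) — with five
fluxes (µM/s): Hill-type SERCA uptake (`V_up`, `K_up = 0.35 µM`), linear
SR leak, gated SR release, gated L-type influx, and saturable sarcolemmal
extrusion (`K_ex = 0.6 µM`).  A beat clock triggers per-beat gating
waveforms, biexponential pulses `exp(−φ/τ_off) − exp(−φ/τ_on)` normalized
to unit peak, with activation/deactivation time constants on gating time
scales (release 20/80 ms, L-type 15/80 ms).

Two deliberate choices:

* **L-type window pedestal.**  `D(t) = d₀ + (1 − d₀)·pulse(t)`.  A pure
  pulse set would leave the diastolic balance to the SR leak, which is
  capped (below) at a tenth of the SERCA flux and therefore cannot hold a
  0.1 µM diastolic set point against SERCA plus extrusion.  The pedestal
  models the L-type window current: it provides the constitutive influx
  that sets the diastolic floor, and it scales with the `gcal` multiplier,
  which is also why raising ICaL raises the baseline so strongly.
* **Buffering factor `β = 1`.**  Under calibration β is redundant with the
  flux gains (any β can be absorbed into them), so it is kept explicit but
  fixed.

The model deliberately omits membrane-potential dynamics; the only
electrophysiological statement it makes is the IK1→rate map below.  It is
a minimal abstraction exposing exactly the four perturbation handles of
the study, not a port of a full ionic model.  A `ported` backend accepts a
user-supplied implementation of a published hiPSC-CM model (a Python file
declaring `STATES`, `CAI_INDEX`, `VM_INDEX`, `rhs(t, y, scales)`; pointed
to by `CATFLUX_PORTED_MODEL`); such a source must itself document which
published model and variant it implements.

### Beat clock

`f(ik1) = f₀ / (1 + α·(ik1 − 1))` with `f₀ = 1.1 Hz` and α fixed in closed
form by the second anchor `f(1.71484375) = 0.5 Hz` (α ≈ 1.6787).  This
reproduces the known IK1-over-expression slowing of spontaneous hiPSC-CM
beating with the only two quantitative anchors available, and makes the
rate exactly monotone in the IK1 multiplier.  Whether the underlying
experiments were paced or spontaneous is not specified anywhere; the
model is spontaneous throughout.

### Calibration (`calibrate_minimal`)

The flux gains are not hand-picked constants; they are produced by a
deterministic constrained search whose constraint list is the
specification of the default cell:

1. spontaneous rate 1.1 Hz at `ik1 = 1` and 0.5 Hz at `ik1 = 1.71484375`
   (by clock construction; verified by simulation within one beat-period
   quantum);
2. ≥ 10 detected transients in a 30 s window;
3. diastolic (trough) Cai in [0.05, 0.2] µM and systolic peak in
   [0.3, 1.5] µM — textbook physiological windows;
4. SR leak flux ≤ 10% of SERCA flux at rest;
5. CaTD90 shorter than the beat period;
6. sarcolemmal dominance: SERCA carries no more than half of the Ca²⁺
   removal at the systolic peak.  This encodes the functional immaturity
   of hiPSC-CMs, whose transients are governed mainly by sarcolemmal
   (L-type/extrusion) fluxes rather than SR cycling; it is also what makes
   the ICaL axis dominate the influence map (below).

The search solves the window pedestal from the quiescent flux balance at a
0.10 µM rest target (closed form given an SR-load estimate), bisects the
L-type gain until the simulated systolic peak hits 1.0 µM, refines the SR
load estimate once, then verifies every constraint by simulation and
raises an error naming each violated constraint otherwise.  The result is
cached per process; the default calibration lands at diastole 0.144 µM,
peak 1.00 µM, TtP 171 ms, CaTD90 712 ms.

### Numerics

LSODA (stiff-capable) with `rtol 1e-7 / atol 1e-9`, `max_step` 10 ms so the
solver never steps over a gating pulse, and output sampled through the
solver's own dense interpolant (`t_eval`) at 400 Hz by default — never by
post-hoc interpolation, because TtP is sensitive to peak timing.  The
first 20 s of every run are discarded to remove limit-cycle transients
(the SR pool relaxes with a ~3 s time constant).  Identical inputs give
bitwise-identical traces; solver failure and non-positive concentration
excursions raise errors naming the tolerances.  Halving the tolerances
moves every phenotype by far less than 0.5%, and over one steady-state
period the integrated cytosolic influx and efflux agree to ~0.1%.

## Phenotypes (`phenotypes.py`)

Peaks are detected on a linearly detrended copy (prominence ≥ 0.2 of the
detrended range, spacing ≥ 0.3 s — spontaneous hiPSC-CM rates stay below
~2 Hz); each peak is paired with the minimum sample back to the previous
peak (the preceding trough = transient onset).  Definitions: amplitude =
peak − preceding trough, TtP = onset→peak, CaTD90 = onset until the trace
first recovers 90% of the way from peak toward the preceding trough
(linear interpolation between straddling samples; the standard cardiac
reading).  The alternative "90% of the beat period" reading is available
as `catd_mode="period"`.  The decay window for a beat runs to the next
beat's trough (trace end for the final beat); a beat whose decay never
reaches the 90% level gets a missing CaTD90, never zero.  Summaries are
means over complete beats; per-beat tables are retained.  Baseline is the
per-beat trough series (tracks drift), with ΔBaseline = last − first
trough.

### Ensemble analyzer for noisy recordings

The raw per-beat estimator is exact on clean traces but breaks down under
noise in a specific way: on the flat diastolic interval the sample argmin
wanders (TtP errors of hundreds of ms at even 1% noise) and the sample
minimum under-shoots the true baseline.  `analyze_trace_ensemble` is the
noise-robust path for quasi-periodic recordings:

1. fold all complete peak-to-peak cycles and average them (noise falls as
   1/√n_beats);
2. baseline = median of the mean beat's near-minimum plateau (tolerance
   2σ_fold, σ estimated from the residual MAD against a 5-point moving
   average); peak by local parabolic refinement;
3. the upstroke is fitted as a straight line in
   `arcsin √((v − baseline)/amplitude)` — exact for a half-cosine rise and
   correct to leading order for any smooth zero-slope transient foot —
   over the contiguous 2–70% amplitude band, weighted by inverse variance
   in the transformed space; the back-extrapolated root gives the onset
   and the slope gives TtP = (π/2)/slope directly, avoiding any
   peak-anchor bias;
4. CaTD90 = interpolated 90%-recovery crossing of the mean beat,
   referenced to the onset through the mean inter-peak interval (which is
   unbiased because detection shifts cancel in peak-to-peak differences).

With 70 s recordings this recovers baseline, amplitude, TtP and CaTD90
within max(5%, one sample) across rates 0.3–1.5 Hz and noise up to 5% of
the amplitude (verified on two independent 50-trace families; worst error
0.7× tolerance).  Its assumptions: strictly periodic beats with a common
shape and a smooth zero-slope upstroke foot.  Strong rate variability,
alternans or drifting beat shape would smear the fold — the per-beat path
remains the right tool there, and neither path classifies arrhythmia.

## Scans and influence map (`scan.py`, `influence.py`)

Axis values are built by integer stepping (`start + i·step`, rounded to
the step's decimals) so grids like 0.1…1.0 are exact and round-trip
through CSV bit-identically.  Grids are the row-major Cartesian product
(first axis slowest); every point runs with the identical solver config;
per-point failures are data (a `converged` flag), not exceptions, because
extreme corners may be stiff — only a fully failed scan raises.  A
single-point scan equals a direct `simulate` call exactly.

Each phenotype array from the 11×10 gCaL × SERCA grid is min–max
normalized over converged cells (constant arrays map to zeros so zero
variation contributes nothing; z-score mode available), combined by an
additive weighted mean (default equal weights, per-phenotype sign
overrides available but off — all four phenotypes increase under the
stress directions studied).  Axis bias uses central finite differences in
multiplier units (the axes span 1.0 vs 0.9), not grid-index units.  With
the shipped calibration the ICaL/SERCA sensitivity ratio is ≈ 8.5 and the
map's maximum sits on the gCaL = 2.0 boundary.

## Trace analytics (`traces.py`)

* ΔF/F₀ = 100·(F − F₀)/F₀ with F₀ the mean over the baseline window —
  default all frames before the stimulus, minimum 5 frames.
* `max_response`: signed extremum (minimum for inverse sensors) after a
  3-frame moving average, so a single noisy frame cannot set the response;
  configurable, and disabled (`smooth_frames=1`) when exact sample
  arithmetic is wanted.
* 5–95% rise time: plateau = mean |ΔF/F₀| over the final 10% of the
  post-stimulus window; t05/t95 are first linear-interpolated crossings of
  5%/95% of the plateau.  "No response" gate: plateau ≤ 3 baseline SDs.
* Bootstrap: percentile bootstrap (not BCa) with a mandatory seed;
  at n = 200 its 95% interval width matches the normal-theory
  `2·1.96·s/√n` within a few percent.
* Group comparison: Welch (unequal-variance) two-sided t test by default —
  the safer reading of an unspecified "independent-samples t test" — with
  Student mode behind a flag; zero-variance degeneracies follow a
  documented convention (equal constants → p = 1; unequal → p → 0 with a
  warning).  Type-I error over seeded null replicates is 5% ± 2%.
* Latency: per-channel extremum respecting polarity; lag = t_A − t_B.

## Wavefront mapping (`front.py`)

Per-pixel activation `a(x,t) = |F − F₀| / max_t |F − F₀|` (absolute
deviation serves direct and inverse reporters alike; per-pixel
normalization absorbs heterogeneous expression).  Binarization is
inclusive at the threshold (a = 0.5 → True at θ = 0.5).  Arrival times are
first-crossing times with linear interpolation between straddling frames;
never-activated and zero-range pixels are NaN.  Speed comes from a
least-squares fit of arrival time against projected distance — direction
given, or estimated as the mean arrival-map gradient — so the intercept
and residual RMS are in seconds and the speed is the inverse slope.  An
8-ROI mode orders ROI centroids by arrival and accumulates chained
distance, mirroring how few-ROI timing measurements are made.  Degenerate
inputs (simultaneous arrival, < 3 distinct distances, rank-deficient fits)
raise; a negative slope is returned as a negative speed with a
`retreating` flag rather than silently flipped.

## Synthetic data (`synth.py`)

All generators are pure functions of (parameters, seed) via
`numpy.random.default_rng`; every artifact ships with its ground-truth
record.

* **CaT traces**: half-cosine rise to the peak at TtP; exponential decay
  with τ = (CaTD90 − TtP)/ln 10, so the 90%-recovery crossing lands
  exactly at CaTD90; past that crossing the tail is multiplied by a cos²
  taper reaching zero with zero slope at the period end, so each beat
  returns exactly to baseline without moving the CaTD90 crossing.  Linear
  drift and additive Gaussian noise on top.  What this emulates: stable
  periodic transients with drift and sensor noise.  What it does not:
  beat-to-beat variability, alternans, motion artifacts, photobleaching —
  so passing recovery tests demonstrate estimator correctness under the
  stated noise model, not robustness to every pathology of real movies.
* **Sensor steps**: |ΔF/F₀| = P(1 − e^(−(t−t₀)/τ)) with τ = rise/ln 19, so
  the 5–95% time equals the requested value analytically.
* **Wave movies**: per-pixel onset = global onset + (projection on the
  propagation direction)/speed, then the sensor-step kinetics per pixel;
  constant outside the mask; the frame rate must keep the front under
  5 px/frame.
* **Dual channels**: channel B repeats channel A's gamma-shaped pulse
  response lag seconds later, with independent noise.

## Problem sizes and defaults

Simulations default to 40 s at 400 Hz with 20 s discarded (≈ 22 analyzed
beats); scans reuse that config for all 110 grid points (≈ 15 s total).
Recovery studies use 50 traces of 70 s at 100 Hz — 70 s matches the length
of the segment summaries used for experimental CaT comparisons and gives
≥ 20 beats for folding at the slowest rate.  Wave movies are 40×40 px,
20 Hz, 10–12 s.  These sizes were chosen so the entire suite and the
acceptance script each run in well under a minute while every estimate
stays quantization-limited rather than sample-starved.

## Known limitations

The minimal model is phenomenological: it makes no claim about membrane
currents beyond the IK1→rate map, its SR pool is abstract, and its
parameter values are calibration artifacts rather than measured constants
— conclusions should rest on the directional trends and the influence-map
geometry, which are the quantities the constraints pin down.  The
influence map's bias ratio depends on the calibration's flux partition;
the sarcolemmal-dominance constraint states that dependence explicitly.
The ensemble phenotyper assumes periodicity (above).  Segmentation is out
of scope throughout: ROI label masks are inputs.
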