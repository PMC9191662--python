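# Methods

This note records the models implemented in `hemokymo`, the defaults and
their rationale, what the simulator does and does not emulate, and the
numerical choices a maintainer would otherwise have to reverse-engineer.

## Imaging geometry and the measurable-speed bound

A FACED mirror pair with input convergence angle Δθ, misalignment α and
separation S produces N = ⌊Δθ/α⌋ virtual sources with interpulse delay
2S/c. `faced_geometry` evaluates both with c = 2.998×10⁸ m/s and reports
the delay to 3 significant figures (1°/0.0125° → 80 foci; S = 300/225/150 mm
→ 2.00/1.50/1.00 ns). A small epsilon (10⁻⁹) is added before flooring so
exact ratios are not lost to binary round-off.

Velocity from a kymograph requires at least two samples per cell inside
the focal array, so displacement per sample can be at most half the
array length h: `max_measurable_speed` returns v = f·h/2. It is exact
arithmetic, in mm/s for f in Hz and h in µm.

## The simulators

All generators take a dataclass spec plus an integer seed and return the
rendered data together with a `GroundTruth` carrying trajectories,
per-frame velocities, event times, gain and motion traces. Identical
spec + seed is bit-identical.

**Kymograph** (`simulate_kymograph`). Cells are 1D segments of length
6 µm with error-function edges (softness 0.5 µm) advected by the
trapezoid-integrated velocity function over a periodic segment; a cell
leaving one end re-enters at the other, and is rendered at s and s ± L so
streaks wrap continuously. Intensity is
background·(1 − contrast·occupancy); occupancy is clipped at 1 where
cells overlap. The noiseless line mean therefore equals
background·(1 − contrast·occlusion_fraction) exactly, which the tests
assert to 1e-9 (photon conservation). Defaults (1 kHz lines, 0.5 µm/px,
50-µm line, 100 cells/mm, contrast 0.8, 200 counts) describe a
single-file capillary recorded by a 50-µm focal array.

**Vessel video** (`simulate_vessel_video`). Cells are disks of radius
3 µm (erf edges) seeded uniformly over the circular lumen cross-section
(chord density ∝ √(R²−r²)); each is advected along the axis polyline at
V(r) of its own radial offset, where
V(r) = Vmax[1 − (1−β)|(r−r₀)/R|^B], multiplated in time by
1 + Σₖ mₖ sin(2πk f₀ t). Single-file mode (all r = 0) engages when the
cell diameter reaches the lumen diameter. The scene is composed as
outside·texture·(1−lumen) + plasma·lumen, darkened by cell occupancy,
then shifted rigidly per frame (whole-frame motion), multiplied by the
per-column FACED gain, and finally passed through the noise model.
`outside_texture` adds a static speckle pattern to the parenchyma
(σ = 1 px smoothed Gaussian field); it is off by default and exists
because rigid registration — like in vivo — needs static texture to lock
onto; without it the only static features are the smooth vessel walls.
The FACED gain is a length-W per-column profile applied to every row:
the pulse intensity varies along the focal array (the fast axis), not
across galvo positions.

**Penetrating-vessel trace** (`simulate_penetrating_trace`). Poisson
transit times at `mean_flux`; each transit is a Gaussian dip of
fractional depth `dip_depth` whose two edges have width `transit_sigma`
(default 2 ms). A warning fires when the expected gap drops below 4σ,
where merged dips become likely. Defaults (50 cells/s, 60% depth,
200-count baseline) are typical of a cortical capillary at 1 kHz.

**Bifurcation images / multifile line scans.** Convenience generators
render parent/daughter cross-section images from one Poisson event
stream routed multinomially (so flux conservation is exact in truth),
and megahertz line scans with separable Gaussian blobs per transit at
random lateral positions.

What the simulator does **not** emulate: optical point-spread functions
and axial sectioning, fluorescence lifetime effects, cell deformation and
crescent shapes in fast flow, hematocrit-dependent optical screening,
non-rigid tissue motion, and line-to-line (intra-frame) motion. Passing
tests therefore demonstrate the correctness of the estimators under the
stated image-formation model, not robustness to every in vivo artifact.

## Normalization, binning, registration

The gain estimate for a kymograph is its time-summed trace; for a 2D
stack, the rows of the time-averaged frame are ranked by summed signal,
the 10 brightest are summed along the slow axis, and the resulting
per-column trace divides every row. The trace is rescaled to unit mean
over included columns so normalization preserves the overall brightness
scale (the scale convention is otherwise arbitrary). Columns whose
correction would exceed a 5× boost — dim FOV edges — are flagged
`excluded` and keep their raw values; the exclusion set and mean are
iterated to a fixed point. Normalization is idempotent on included
columns to <1e-6. PIV masks excluded columns by replacing them with the
per-line included mean, which is correlation-neutral.

`bin_time` is a non-overlapping mean with the trailing remainder
dropped and the rate divided by the factor (a 1-MHz line scan binned 10×
becomes 100 kHz, the configuration used before PIV on megahertz data).

`register_rigid` estimates per-frame translation by phase correlation
against a reference (temporal mean, or a chosen frame — frame references
are preferable under large step-like motion, where the mean image is
multimodal) with 10× upsampled subpixel refinement, then shifts frames
by bilinear interpolation with replicate padding. Featureless frames
fall back to zero shift with a warning. Expected accuracy on textured
scenes is ≲0.1 px; the tests require <0.25 px RMS on square-wave motion
and inverse-consistency of the same order.

## Kymograph extraction

Polyline ROIs ((x, y), 0-based, origin top-left, stored as CSV with
header `x_px,y_px`) are resampled at uniform arc-length spacing (default
1 px) and sampled per frame by bilinear interpolation; an optional
band-average width samples parallel offset lines and averages. The
kymograph inherits the frame rate as line rate; spatial sampling is
spacing × pixel size. Positive velocity means motion toward increasing
arc length, so reversing an ROI flips the sign downstream. The cross-line
for diameter measurements should be drawn at ~1-px spacing: sub-pixel
bilinear sampling introduces interpolation kinks that perturb the
derivative extrema used for edge detection.

## PIV

For each window (default 2 ms, stride 0.2 ms — 5 estimates/ms), every
line is paired with the line `line_lag` later (default 1). The
correlation is a proper normalized cross-correlation evaluated on the
overlap region of each lag (overlap means and energies come from FFT
correlations with a box kernel). This matters at both extremes: global
normalization biases small displacements toward zero and lets spurious
small-lag peaks beat genuine large displacements near the search bound.
Correlograms are averaged over the window's line pairs; the peak is
refined by a three-point parabolic fit (centroid refinement available).
Velocity = displacement · pixel_size · line_rate / line_lag, reported in
mm/s. Windows are flagged NaN when featureless, when the peak
correlation falls below `min_quality` (default 0.1), or when the peak
sits at the search boundary |d| = X/2 (out-of-range flow is reported
missing, not clipped). Measured accuracy on noiseless synthetic
kymographs is ≤0.2% for velocities up to 0.8× the bound.

The Radon estimator takes the projection angle that maximizes the
sinogram column variance (0.5° grid, inscribed circle); the streak slope
is tan θ in px/line, calibrated on synthetic streaks of known slope.
Windows without a dominant angle (variance ratio < 2.5 over the median)
return NaN. Near the measurement bound the angle grid quantization makes
it markedly worse than PIV, which the tests demonstrate.

## Dense SIFT flow

Descriptors are dense orientation histograms: gradient magnitude
soft-assigned to 8 orientation bins, box-aggregated over 2-px cells,
sampled on a 4×4 cell grid around each pixel (128 dims), L2-normalized
with 0.2 clipping, and scaled to the 0–255 convention of the reference
implementation — the published weights (η = 0.01, α = 50, d = 10020)
assume descriptor distances on that scale. Descriptors are exactly
invariant to additive brightness shifts and nearly invariant to contrast.

The flow minimizes the truncated-L1 energy over integer displacements
within a search window (default 10 native px) on frames up-sampled 2× by
cubic interpolation; the result is divided back, giving half-pixel
quantization. The optimizer is synchronous min-sum loopy BP with
distance-transform messages (O(labels) per message), message damping 0.5
(synchronous updates otherwise oscillate on flat energy landscapes), and
normalization by the message minimum. The best labeling over iterations
is returned and is never worse than the zero field, which seeds the
search — this makes the energy-decrease guarantee E(w) ≤ E(0)
unconditional. The data truncation t defaults to the 95th percentile of
per-pixel best-match distances because the reference default is not
recoverable; it is configurable. Pyramid depth defaults to 1 (the frame
sizes this package targets rarely need it); deeper pyramids use
warp-and-refine with rounded coarse flow. An exact row-transfer dynamic
program (`exact_min_energy`, exponential in the narrow grid side, usable
to width 4) serves as the optimizer's oracle on small instances; on the
tested instances BP attains the exact minimum.

ROI polygons mask the reported fields only — never the optimization —
because the smoothness term deliberately propagates flow into
featureless regions (dim parenchyma), which is spurious for reporting
but harmless for matching. Line-ROI RBC velocity is the maximum flow
magnitude along the line (plasma moves slower than cells), signed by the
projection onto the line tangent.

## Diameter and profiles

Diameter: the intensity profile across the vessel is cubic-spline
up-sampled 10×; the two positions of maximal-magnitude, opposite-sign
derivative are the edges and their separation (µm) the diameter. For a
Gaussian band of width σ this returns 2σ (the inflection points), a
closed-form check in the tests. Flat or monotone profiles raise.

Radial profiles displace the axis polyline along its local normal by
each requested offset (µm), extract a kymograph and run PIV; the profile
point is the time-mean velocity. Near-wall offsets (|r| ≳ 0.7R) are
best avoided: finite cell size lets faster cells dominate the
correlation there and flattens the measured profile.

The blunted-parabola fit holds R fixed (from the measured diameter;
freeing it creates a Vmax–R degeneracy) and fits (Vmax, B, β, r₀) by
bounded least squares (B ∈ (0.1, 50], β ∈ [0, 1], |r₀| < R), multistart
over B₀ ∈ {2, 1, 4} with Vmax₀ = max profile value, β₀ = 0.1, r₀₀ = 0.
Bluntness Vmax/Vavg = (B+2)/(B+2β) corresponds to the **area-weighted**
(disk) average of the profile — `average_velocity` also exposes the
chordal mean Vmax(B+β)/(B+1) for users who want the 1D-line convention;
the bluntness ratio always uses the disk form that matches its closed
form. Bluntness-vs-diameter trends are summarized by ordinary least
squares.

## Flux and half-times

Transit counting smooths the trace with a Gaussian window (width 3
frames; σ = (width−1)/5, the usual Gaussian-window convention), inverts
it and detects peaks with prominence ≥ 3× the MAD of the detrended trace
(floored at 0.1% of the trace range) and separation ≥ 3 frames; both are
configurable, reflecting that these thresholds are dataset-dependent in
practice. Counting is invariant to intensity scaling and offsets.

Half-times: each detected dip is split at its local minimum; each side
is fitted with baseline + A·exp(−(t−c)²/2σ²), A < 0, against a local
baseline (median of a ±40-frame flanking window). The 10→90% duration on
the fitted curve is σ(√(2 ln 10) − √(2 ln(10/9))) = 1.687σ per edge; the
event half-time averages the two edges, skipping an edge truncated by
the record boundary. Velocity = effective length / half-time with a
6-µm default RBC length (µm/ms ≡ mm/s).

Bifurcations: cross-section images are summed over space into 1D traces
and counted identically; the report gives parent flux, daughter sum,
relative error and partition fractions. Multifile line scans are binned
in time until cells are roughly round, inverted, and counted as local
maxima (order-statistic filter: a pixel is an event iff it is its
neighborhood maximum and exceeds median + 3 MAD); merged cells make this
a lower bound of the true flux.

## Pulsatility

Spectra use a mean-removed (optionally detrended) FFT with a Hann window
by default, normalized so that the sum of squared amplitudes equals the
variance of the (window-compensated) trace — with a boxcar window this
is Parseval's identity verbatim, asserted to 1e-6. The cardiac
fundamental is the largest peak in a 5–15 Hz search band (mouse heart
rate), accepted only if it exceeds 4× the broadband median floor —
without this gate a white-noise trace always "finds" a fundamental,
because the band argmax is large by construction. Harmonics k·f₀ are
detected when their local amplitude exceeds 3× the median floor of the
surrounding neighborhood; band widths are reported at half prominence.

The pulsatility index band-passes the trace around f₀ (2nd-order
Butterworth, 0.5–1.5 f₀, zero-phase), segments cycles peak-to-peak
(boundary cycles are dropped when enough remain, because zero-phase
filtering distorts the record edges by a sample), and averages
(Vpeak − Vmin)/Vmean over cycles on the raw trace. For
v(t) = v₀(1 + m sin 2πf₀t) this gives exactly 2m when the sampling grid
hits the extrema, which the acceptance test asserts to 1e-6. A trace
with no detectable oscillation returns PI = 0; an oscillating trace with
fewer than 3 complete cycles raises. Measurement noise biases PI upward
(noise inflates per-cycle extrema); longer windows or cycle averaging
reduce the bias.

Correlation matrices are plain Pearson correlations of mean-removed
traces on a common grid; zero-variance traces get NaN rows/columns with
a unit diagonal.

## Pipeline and reproducibility

`run_pipeline` executes a YAML-declared stage list in order inside a run
directory, hashes every written file (SHA-256) into `manifest.json`
along with the config hash and seed, and rejects unknown config or stage
keys by name. All random stages derive from the single pipeline seed, so
rerunning a config reproduces the manifest bit for bit.

## Problem sizes used in the test suite

Simulated records in the tests are deliberately small — e.g. 0.3–0.5 s
vessel videos at 1 kHz, 40×96 to 56×96 px FOVs, 22-frame SIFT-flow
series at 500 Hz, 0.4–10 s penetrating traces — chosen as the smallest
sizes at which each estimator's statistical tolerances are meaningful.
The estimators themselves carry no size assumptions beyond those stated
(window lengths, descriptor support, minimum cycle counts).

## Known limitations

* PIV reports one velocity per window; strongly sheared single-file
  kymographs with multiple simultaneous speeds yield the dominant one.
* The SIFT-flow optimizer is discrete; sub-half-pixel flow requires a
  larger upsample factor at quadratic cost in labels.
* Near-wall radial-profile points are biased by finite cell size (see
  above); fits should use offsets within ~0.7R.
* The multifile counter undercounts overlapping cells by construction;
  its output is a lower bound.
* Registration assumes whole-frame rigid translation; rotation and
  line-by-line motion are out of scope.
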