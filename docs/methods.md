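# Methods

## Overview

`adhescan` quantifies single-cell adhesion from two complementary
measurements and ties them together:

1. **Label-free biosensor imaging.** A resonant waveguide grating (RWG)
   imager reports, per 25 µm pixel, the shift of the resonant wavelength
   (WS, in pm) caused by mass redistribution within ~150 nm of the sensor
   surface. Adhering, spreading cells appear as bright bumps in the WS
   image. The per-cell adhesion proxy is the integrated wavelength shift

       IWS = A_pix · Σ_{i : WS_i > threshold} WS_i        [pm·µm²],

   where `A_pix` is the (interpolated) pixel area and the sum runs over
   the above-threshold pixels of the cell's segment.

2. **Fluidic force microscopy (FluidFM).** A hollow cantilever grabs a
   cell by suction and detaches it while recording a force-distance
   curve, yielding the adhesion force (nN) and adhesion energy (pJ).

Measuring both on the same cells gives a linear calibration F = s_F·IWS,
E = s_E·IWS, after which the imaging channel alone reports adhesion
force/energy kinetics for hundreds of cells in parallel.

## Segmentation and thresholding

A frame is bilinearly refined (`interpolate_frame`): each grid interval
is subdivided into 2^k parts, so the pitch becomes `pitch/2^k` (k = 4 →
1.5625 µm from a 25 µm grid). Refinement preserves the original node
values exactly; its purpose is sub-pixel localisation of the cell
boundary, and the measured IWS stabilises once the interpolated pixel is
small relative to the cell (changing k by 1 moves IWS by < 2%).

Cell centres are strict 8-neighbour local maxima of the interpolated
frame rising at least `min_prominence` above the frame median (the
background level; default 3× the robust background SD). Maxima closer
than `min_separation` (default 50 µm) are greedily pruned, higher peak
wins. The frame is then partitioned by a Voronoi tessellation of the
centres — every pixel joins its nearest generator, equidistant pixels
the lowest generator index. The assignment is computed exactly in
integer arithmetic, so the partition is fully deterministic.

Each segment receives its own threshold. The *adequate threshold* (AT)
of a cell is defined operationally: the WS cutoff at which the cell's
above-threshold area equals its brightfield footprint area
(`find_adequate_threshold`, a bisection on the monotone threshold↦area
map, tolerance one interpolated pixel area). Across cells AT follows a
saturation law in the segment's maximal pixel value WS_m,

    AT(WS_m) = a·WS_m / (b + WS_m),

fitted by nonlinear least squares (`fit_at_model`; initial guess
a₀ = max AT, b₀ = median WS_m, parameters constrained positive). Once
(a, b) are known, thresholds for all further cells come from the
biosensor image alone. The reference parameterisation used as the
synthetic generator's truth is a = 3128 pm, b = 2935 pm.

For whole-stack tracking (`extract_tracks`) centres are detected on the
final frame — where cells are brightest — and held fixed; cells are
assumed non-migrating over the ~90 min experiment. Segments whose WS_m
stays below a noise floor (max(5× background SD, 100 pm)) are discarded
as noise peaks.

## Force-curve evaluation

Raw photodetector voltages convert to force as psd (mV) × sensitivity
(m/V) × spring constant (N/m); the sensitivity comes from first-order
polynomial fits to hard-contact approach curves (mean of the fitted
slopes), the spring constant is an instrument input. `evaluate_fd`
rebases the retraction curve so its final sample reads 0 nN, takes the
magnitude of the absolute minimum as the adhesion force, and integrates
|force| over z between the zero crossings bracketing the minimum
(linear-interpolated crossings, trapezoidal quadrature) as the adhesion
energy; 1 nN·µm = 1 fJ. The integration uses |force| over the retraction
coordinate; this sign/variable convention is recorded here because the
signed alternative differs for curves that overshoot the baseline.
Probe limits follow from the hardware: holding force
f_max = |P|·π(d/2)² (700 mbar on an 8 µm aperture → 3.5 µN) and loading
rate = spring constant × retraction speed.

## Calibration and population statistics

`fit_calibration` estimates zero-intercept least-squares slopes for
force-vs-IWS and energy-vs-IWS (zero IWS must map to zero force; a
free-intercept fit is reported as a diagnostic only) with slope standard
errors and Pearson correlations. Reference slopes:
4.9×10⁻⁴ nN/(pm·µm²) and 6.4×10⁻⁶ pJ/(pm·µm²).

Per-cell kinetics are summarised by a 3-parameter logistic
E(t) = E_sat/(1+exp(−r(t−t₀))) (`fit_sigmoid`; the simplest sigmoid
with a rate constant and a saturation value; typical values 15 pJ and
0.005 1/s). Population snapshots are summarised by log-normal fits via
log-moment MLE (`fit_lognormal`: µ = mean ln x, σ = population SD ln x),
chosen over quantile matching for determinism and closed forms
(mean = e^{µ+σ²/2}, mode = e^{µ−σ²},
variance = (e^{σ²}−1)e^{2µ+σ²}). `population_timecourse` applies the
fit per frame to cells above a detection floor — by default the
calibrated force of a one-raw-pixel segment at the 100 pm noise floor
(≈30 nN at the reference slope) — and emits under-populated frames as
missing, not zero. `compute_spectrogram` bins per-cell values into
time × value histograms normalised per time bin; stored frequencies are
linear, log colour-scaling is presentation only.

## Synthetic data generator

No public combined RWG/FluidFM dataset exists, so the generator is the
test bed. It emulates:

- **Cells** as radial Gaussian bumps truncated at a support radius R
  (σ = 0.4 R, so the truncation edge carries 4.4% of the peak), with a
  logistic amplitude time course normalised to reach the drawn final
  peak exactly at the last frame. Centres are snapped to sensor pixel
  centres, placed by rejection sampling with a minimum separation and
  fully inside the grid.
- **Defaults** (one 2×2 mm sensor, 80×80 px at 25 µm, 3 s frames,
  90 min): 300 cells; final peak WS log-normal with median 2600 pm and
  σ_log = 0.35 — placing the median cell's final adhesion energy near
  the typical 15 pJ saturation; support radius 45 ± 6 µm; rate
  0.005 ± 0.0015 1/s; spreading midpoints 1200 ± 400 s; minimum
  separation 55 µm (at 75 cells/mm² larger separations are
  geometrically infeasible); i.i.d. Gaussian pixel noise, SD 30 pm — an
  explicit setting, since baseline noise is instrument-specific.
- **Ground truth in closed form.** With threshold ratio
  ρ = AT(A)/A = a/(b+A), the above-threshold radius is
  r_th = σ√(2 ln(1/ρ)) (clipped at R), the true area π r_th², and the
  true IWS 2πσ²(A − AT(A)) (or 2πσ²A(1−e^{−R²/2σ²}) when clipped).
  True force/energy follow from the generator's calibration slopes.
  Brightfield-style masks are discs of radius r_th at the final frame,
  rendered at 2 µm pixels.
- **FD curves** as a zero baseline with a triangular or sin² dip of
  depth f_adh whose area is e_adh (width 2E/F); triangle breakpoints
  are inserted into the sample grid so trapezoidal evaluation recovers
  both values exactly in the noiseless case.
- **Calibration tables** with IWS uniform on [2×10⁵, 4×10⁶] pm·µm²
  (the instrument's usable force range at the reference slope) and
  independent multiplicative Gaussian noise; at 25% relative noise the
  induced Pearson correlations land around 0.86–0.92.

All generators are deterministic given a seed
(`numpy.random.default_rng`).

### What the generator does not emulate

Real cell morphology (bumps are radially symmetric), migration between
frames, spatially correlated sensor drift, debris and optical
artefacts, and cantilever dynamics beyond an additive noise band on the
FD curve. Passing tests therefore demonstrate correctness of the
algorithms under the stated model, not robustness to every failure mode
of real recordings.

## Numerical choices and limitations

- **Sampling limit of the coarse grid.** A bilinear surface through
  25 µm samples underestimates the integral of a Gaussian bump whose σ
  is comparable to the pitch, and just above threshold onset the
  above-threshold cap is smaller than the sampling scale entirely. The
  ground-truth reproduction test therefore uses a well-sampled cell
  (σ/pitch ≈ 3.6) and asserts the 5% band from the spreading half-time
  onward; at typical HeLa geometry (σ ≈ 18 µm on a 25 µm grid) measured
  IWS carries a systematic negative bias of order 10–20%, which the
  downstream calibration absorbs into its slopes (both channels see the
  same bias). This is a property of the instrument geometry, not of the
  algorithm.
- **Ties and determinism.** Voronoi ties go to the lowest generator
  index; centre pruning orders by descending value then row-major
  position; bisection returns the bracket midpoint when the discrete
  area function jumps over the target.
- **Degenerate inputs** are flagged, not silently fitted: constant
  series (rate unidentifiable), all-equal log-normal samples (σ = 0),
  rank-deficient calibration designs, flat sensitivity curves, all-zero
  FD curves.
- **Problem sizes.** The shipped end-to-end configuration processes the
  300-cell, 90-min stack at every 20th frame (3 s native sampling →
  60 s processed), which resolves the spreading kinetics (rate
  0.005 1/s → ~200 s rise time) while keeping a full run around a
  minute on one CPU. Native-rate processing scales linearly in the
  frame count.
- **Approximate log-normality.** The saturating threshold law makes the
  final force sample a nonlinear transform of the log-normal amplitude,
  so log-normality of forces is approximate (good at fixed footprint,
  mildly skewed otherwise) — consistent with its use as an empirical
  description rather than a derived law.
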