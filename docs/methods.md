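# Methods

This note documents the models, numerical choices and limitations of the
`dropscreen` pipeline. It is written for users who want to know what the
computations assume, not how the code is organized.

## Flow programs and concentration mapping

A screening plan fixes four channel flows: carrier liquid (136 µL min⁻¹),
cell suspension (32), and an aqueous dosing budget (32) shared between the
effector syringe(s) and plain medium, for a constant 200 µL min⁻¹ total.
Droplet composition follows from steady-state mass balance over the
aqueous channels only (the carrier is immiscible):

    c(t) = c_stock · f_eff(t) / (f_cells + f_dosing) = c_stock · f_eff(t) / 64

With a 2× stock, a 1D ramp of the effector flow from 0 to the full
32 µL min⁻¹ spans 0–100% of the intended maximum; in 2D each effector can
use at most half the dosing budget (16 µL min⁻¹), so 4× stocks restore the
same 0–100% span per axis. This is the only dilution model consistent with
the 2×/4× stock convention, and it is applied uniformly in design
(`gradient_design`) and annotation (`screening_analysis`).

Design choices:

- The 1D ramp is **linear in time**. Any monotone profile would work; the
  linear ramp spreads droplets uniformly over the percent axis, which is
  what makes equal-width bins equally populated (~13.75 droplets/bin at
  440 droplets and 32 bins).
- The 2D grid is enumerated **row-major with effector A outer**. The order
  is recorded in the program metadata so no downstream step ever relies on
  it.
- Droplet cadence is the aqueous volumetric rate divided by the droplet
  volume: 64 µL min⁻¹ / 500 nL = 128 droplets min⁻¹, i.e. a 0.469 s
  period; a 440-droplet 1D sequence takes 3.44 min and the 968-droplet
  11×11 grid (8 droplets per cell) 7.56 min. Each droplet is timestamped
  at the midpoint of the aqueous volume interval it collects, which places
  exactly `droplets_per_step` droplets inside each 2D dwell period.
- The cost calculator treats one droplet as the functional equivalent of
  one microtiter well (200 µL, 96-well plates) and reports plate counts as
  exact ceilings (1000 wells → 11 plates).

## Synthetic droplet trains

The simulator's job is to produce traces with the statistical structure
the analysis assumes — not to model cyanobacterial physiology. Its
defaults encode the platform's standard operating point: 500 nL droplets,
Poisson cell loading with mean volume × 10 cells nL⁻¹ (5000 cells per
droplet), 7-day incubation with daily measurement, 250 Hz sampling.

**Growth model.** Cell count follows a closed-form logistic from the end
of a lag phase, with realized rate

    r = r_max · min_e [ c_e/(c_e + K_e) · 1/(1 + exp(s_e (c_e − θ_e))) ]

i.e. Monod limitation times smooth (logistic) inhibition per effector,
combined across effectors by a Liebig minimum. This is the simplest form
that yields (a) a unimodal 1D dose response with a peak strictly between
K and θ, and (b) a 2D surface where only raising both nutrients together
gives high growth. Parameters of the canonical screens (chosen once, as
part of the study conditions, with rationale):

| parameter | 1D nitrate screen | 2D N×P screen | why |
|---|---|---|---|
| r_max (day⁻¹) | 1.2 | 1.2 | ~14 h doubling at optimum, mid-range for cyanobacteria |
| capacity (cells nL⁻¹) | 2000 | 2000 | keeps day-7 endpoints below saturation so dose differences stay visible |
| lag (days) | 0.5 | 0.5 | short acclimation |
| K (mM) | NaNO₃ 4 | NaNO₃ 4, K₂HPO₄ 0.08 | half-saturation well inside the tested range |
| θ (mM) | NaNO₃ 16 | NaNO₃ 60, K₂HPO₄ 2 | 1D: K and θ bracket a ~10 mM optimum; 2D: no inhibition inside the 0–30 / 0–0.5 mM window |
| steepness (mM⁻¹) | 0.5 | 0.3 / 5 | inhibition width a few mM (1D), scaled to each axis (2D) |

**Optics.** Each droplet renders as a rectangular plateau pulse whose
width is the plug passage time, length/velocity with length = V/(πr²) in
the 1.0 mm ID detection tube: 500 nL at 200 µL min⁻¹ gives 0.15 s
(~37.5 samples). Pulse height per channel is
`offset + gain · cell density`; the offset is the blank-droplet signal
(refractive-index step aqueous/carrier), so empty droplets are still
detectable. Defaults: carrier baseline 0.05 a.u., absorbance offsets
0.40–0.50 a.u., autofluorescence offset 0.02 a.u., gains chosen so a
day-7 dense droplet (~10³ cells nL⁻¹) reads a few a.u. Noise terms, all
configurable: additive Gaussian noise (SD 0.01 a.u., giving ~50:1
pulse SNR so detection at k = 5 is clean), per-droplet-day lognormal
height heterogeneity (10%, modeling inhomogeneous cell distribution),
optional linear baseline drift (off), Gaussian pulse-edge smoothing
(σ = 2 samples), 2% lognormal droplet-volume jitter. Detector pulse
shapes and noise levels of the real instrument are not published;
these defaults are declared, not inferred.

What the simulator deliberately does **not** model: absorbance spectra
and path-length photophysics (one gain per channel), evaporation, gas
exchange, droplet coalescence/splitting (available behind the volume/
count knobs but off by default), pump transients and Taylor dispersion in
tubing. Passing tests therefore show the *pipeline* is correct under the
stated statistical structure, not that the biology of any real strain is
reproduced.

## Droplet detection

- Baseline: candidate pulse samples are flagged on the reference channel
  by a median + 5·MAD rule; level (median) and SD are then computed per
  channel over the remaining carrier samples. At least 1 s of carrier
  signal is required.
- Detection gates on the **750 nm absorbance channel** — the channel
  least affected by pigment composition — with threshold
  `level + k·SD`, k = 5 by default, minimum run width 10 samples
  (40 ms, ~¼ of a nominal pulse). Partial pulses touching the trace edges
  are discarded and logged. Raising k can only remove runs, never split
  rectangular pulses, so droplet count is monotone in the threshold.
- Droplet **size** is the passage time. Run boundaries are refined to the
  samples where the background-subtracted reference signal reaches half
  the pulse peak; for an edge-smoothed pulse the threshold-crossing
  interval overestimates the plug length whenever the threshold sits low
  on the edge (by ~2σ·Φ⁻¹(1−thr/h) samples), while the half-maximum
  interval is unbiased for symmetric edges and leaves rectangular pulses
  untouched. `end_sample` is inclusive, so `size = (end − start)/f_s` and
  the trapezoidal integral of a flat pulse divided by size equals its
  height exactly.
- **Intensity** is the trapezoidal integral of the background-subtracted
  signal over the droplet divided by its size (a size-referenced mean),
  making the readout invariant to droplet-size jitter. The raw
  (non-normalized) integral is available via `size_referenced=False`.
  Negative values are *not* clipped; a droplet dimmer than the carrier
  baseline stays negative and is excluded only at the NFU stage.

## Growth readout and aggregation

NFU is computed per droplet: droplets are paired across measurement days
by ordinal position, justified by the conserved droplet order in the
storage coil (verified in simulation: count and order are conserved by
construction, and detection recovers all droplets at default noise). A
count mismatch ≤ 5% truncates both sequences from the start with a
warning (the excess is assumed lost at the sequence tail); a larger
mismatch aborts the run as coalescence/loss. Droplets with I_t0 ≤ 0 have
undefined NFU and are excluded and counted in the QC report.

Dose–response curves use 32 equal-width bins on the percent-of-maximum
axis (3.1% resolution), left-closed right-open with the last bin closed;
SD uses the n−1 denominator everywhere, and binned statistics are
invariant to droplet order. 2D matrices group by exact grid cell; empty
cells are reported as empty (n = 0, NaN mean), never as zero response.

The optimum is reported as a **plateau range**, the contiguous bins
around the best bin whose mean stays within 5% of the maximum, rather
than a bare argmax — dose–response maxima are typically flat-topped and a
single-bin answer would be noise-driven. A plateau ending at a boundary
bin is flagged: the true optimum may lie outside the tested range.

N:P ratios are molar nitrate/phosphate rounded to two significant
figures and formatted `R:1`. Endpoint comparisons use an independent
two-sample Student's t-test (equal variances, two-sided, α = 0.05
convention); identical zero-variance groups return p = 1 by convention.
No multiple-testing correction is applied (single planned comparison per
medium).

## Determinism and provenance

Every stochastic step draws from a single `numpy` Generator seeded from
the run config; repeated runs are byte-identical, including CSV output.
Trace CSVs are written with 17 significant digits and read with pandas'
round-trip float parser, so write→read is lossless. Output bundles carry
the seed, a SHA-256 config hash and the package version; QC reports list
per-day droplet counts, count-mismatch warnings, excluded droplets,
baseline statistics and empty cells.

## Problem sizes

The canonical screens used throughout the analysis scripts and tests are
the platform's standard runs: 440 droplets (1D) and 968 droplets (2D,
11×11 × 8), measured on day 0 and day 7 (daily for the 50-droplet growth
kinetics). A full 1D screen simulates ~52,000 samples × 5 channels per
day and completes in well under a second; repeated-seed evaluations (10
runs) complete in seconds.

## Known limitations

- The half-maximum size refinement assumes roughly symmetric pulse edges;
  strongly asymmetric detector responses would bias sizes.
- Ordinal day-pairing breaks down under heavy coalescence; the pipeline
  detects this (count mismatch) but does not attempt re-identification.
- The plateau optimum range depends on the 5% plateau fraction; very flat
  responses return wide ranges by design.
- The growth model is phenomenological. Parameter estimates from real
  screens (Monod/Hill fitting) are out of scope.
- The 2D screen's per-axis flow cap (half the dosing budget) means
  combined 100%+100% cells are reachable only with ≥4× stocks; the plan
  validator enforces this implicitly through the stock-factor convention.
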