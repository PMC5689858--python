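# Methods

## The problem

A passively double-scattered proton system delivers a spread-out Bragg peak
(SOBP) selected by a discrete beamline *option* (scatterer + modulation-wheel
combination) plus a range `R` and modulation width `M`, both in g/cm² of
water-equivalent depth and selectable in 0.1 g/cm² steps. The machine counts
monitor units (MU); converting a prescribed dose at a calibration point into
MU requires the *output* Ψ (cGy/MU) at that point, which treatment planning
systems do not predict reliably for this delivery technique. The package
implements three output models for a 24-option machine (large options 1–12
with a 25 cm applicator and a 20×20 cm² reference field; deep 13–17 and
small 18–24 with a 14 cm applicator and a 10×10 cm² reference field) and the
statistics used to validate them against measurements.

Conventions shared by all models:

* **Gantry arc.** The cyclotron rotates with the gantry through 190° from
  355° through 0° (beam facing down, the calibration angle) to 185°. Angles
  are mapped to a signed arc coordinate in [−5°, 185°]; distances and
  interpolation operate on that coordinate, which handles the 355°→0° wrap.
* **Field sizes.** Square and circular apertures are interleaved in one
  table via the equivalent-square side (`D·√π/2` for a circle of diameter
  `D`) — the standard dosimetric convention; the mixing rule is overridable
  by supplying a custom grid.
* **Calibration geometry.** MU calibration is performed at the isocenter and
  SOBP center; a patient plan's calibration point may sit Δz_p from the SOBP
  center (negative downstream, positive upstream, |Δz_p| ≤ 5 cm by default)
  with the SOBP center itself Δz from the isocenter. On the flat SOBP
  plateau the output then changes only through the inverse square of the
  distance to the effective source:
  `ISF_OCF = [(ESAD − Δz_p)/(ESAD − Δz_p − Δz)]²`. The older pair of a
  PDD-based off-center factor and a plain inverse-square factor is kept as
  legacy functions (`sobpocf`, `isf`) for comparison, off by default.
* **ESAD.** One effective source-to-axis distance per option, between
  171.9 cm and 180.8 cm. Only the two extremes are published; the shipped
  catalog therefore leaves the others unset (site commissioning must supply
  them), while the virtual machine assigns an affine-in-range profile
  anchored at the printed extremes. Using one ESAD per option despite the
  small range-dependent source shift contributes < 0.5%: with a 5 cm point
  offset, ESAD 185 vs 180 gives (185/180)² = 1.0563 vs (180/175)² = 1.0580,
  a 0.2% difference.

## Model A — correction-based

`Ψ_A = Ψ₀·ROF·SOBPF·RSF·ISF_OCF·OCR·FSF·GACF`, every factor a measured
ratio to the calibration beam (option 20, R 15.0, M 10.0, 10×10 cm²,
gantry 0°, point at isocenter = SOBP center; Ψ₀ = 1.06 cGy/MU):

* **ROF** (per option, exact lookup): output at the option's deepest range
  relative to the calibration beam.
* **SOBPF** (1-D in M): modulation sweep at the deepest range, measured at
  2, 3, 4 and then every 2 g/cm²; the extra 3 g/cm² point exists because the
  output changes fastest between 2 and 4 g/cm² and linear interpolation
  needs the support there.
* **RSF** (2-D in R×M, bilinear): three ranges per option (minimum, median,
  maximum; the maximum is the reference row, identically 1). Grid cells with
  M > R cannot be measured (the proximal SOBP would extend outside the
  patient; the machine refuses M > R) but bilinear interpolation needs a
  complete rectangle, so those cells are filled by a log fit
  `c₀ + c₁·ln M` to the measured cells of the same row and flagged as
  placeholders. The two-parameter form is the minimal reading of the
  documented "log fit"; the printed placeholder cells are reproduced within
  ±0.02. Any prediction whose interpolation cell touches a placeholder
  corner carries a warning flag.
* **OCR** (2-D lateral, bilinear): one 2-D array acquisition per option,
  normalized to the central axis. Profiles are *not* radially symmetric
  (mirror points can differ by several percent), hence true 2-D
  interpolation. `resample_ocr` converts a coarse array grid (10 mm pitch)
  to the conventional 0.5 mm tabulation; because a bilinear patch restricted
  to a sub-rectangle is still bilinear, interpolating the raw or the
  resampled grid yields the identical surface, so the pipeline stores raw
  grids and resampling is an explicit, optional step.
* **FSF** (1-D in equivalent-square side): measured for three options per
  group; unmeasured options use the nearest measured option in their group.
  Below the smallest measured field the lookup refuses (small-field outputs
  must be measured directly); an explicit override extends the first
  segment and flags the prediction. Fields at or below a 5×5 cm² equivalent
  are always flagged.
* **GACF** (1-D along the arc, per group): the rotating cyclotron changes
  the output with gantry angle — up to 3.6% for small options (peak near
  150°), 2.3% for deep (peak near 135°), nearly flat for large. Measured
  every 15° for one or two options per group and averaged per group.

No factor extrapolates silently; every out-of-grid query raises. Table
bundles round-trip bit-exactly through JSON by default; a `decimals=4`
export reproduces commissioning-report precision.

`MU = D_vpnc / Ψ`, with `D_vpnc` the dose at the calibration point of a
verification plan recomputed in a water phantom without the range
compensator: compensator and patient scatter factors cancel between the
patient plan and that verification geometry, so neither is modelled here.
MU is reported unrounded and rounded to the delivery resolution (0.1 MU
default).

## Models B and C — analytical

The SOBP shape variable is `r = (R′ − M′)/M′` with `R′ = R − 0.31` and
`M′ = 0.81·M` (means over a large body of measured depth-dose scans for
this machine class; both constants are configurable via `RConversion`).
`r = 0` at full modulation; negative `r` (M′ wider than R′) is outside the
model's domain and rejected.

Model B: `Ψ_B = CF·Ψ₀·D_c·100/(1 + a₀ r^a₁)·(s₀ + s₁(R − R_L))·(geometry
factors)`. The amplitude `CF·Ψ₀·D_c·100` is not separately measurable from
output data alone, so the default *absorbed* mode fits it as one constant
and stores it back as `CF` with `D_c = 1` — the formula stays literal, and
sites that measure entrance dose per option can supply `Ψ₀`/`D_c`
explicitly.

Fitting is two-stage:

1. **Basic model.** Nonlinear least squares of `A/(1 + a₀ r^a₁)` on all
   absolute outputs at the option's deepest range (the modulation sweep plus
   the deepest-range range-shifter row — the same readings that build model
   A's tables). Bounded trust-region optimization (a₀ ≥ 0, a₁ ∈ [0.05, 10])
   from (a₀, a₁) = (0.1, 0.6) with five multi-start restarts of a₀ on a log
   grid from 10⁻³ to 10; tolerances 2.3·10⁻¹⁶ so noise-free data is
   recovered to machine precision. Outputs constant across modulation
   degenerate to the a₀ = 0 branch, flagged in the diagnostics.
2. **Source shift.** Each measurement at a non-maximum range is divided by
   the stage-1 basic term evaluated at *its own* r; the line
   `s₀ + s₁(R − R_L)` is least-squares fit to those ratios. Fitting at the
   per-point r (rather than assuming exactly matched r across ranges) makes
   the 0.1 g/cm² rounding of the matched-r design triplet exact. With data
   at a single range the line degenerates to (1, 0).

Model C replaces the basic term by a quartic in r. Two constructions:

* `convert_B_to_C` (**primary**): least-squares quartic fit to a fitted
  model B's basic term sampled densely over the option's commissioned r
  span — the *mathematical conversion*. The quartic tracks the rational
  form to well under 1% over every option's span, and the source-shift line
  carries over.
* `fit_model_C` (direct): linear least squares of the quartic on raw
  outputs, solved on the scaled variable r/max|r| (Vandermonde + QR) so
  exact quartic data is interpolated to linear-algebra precision. This
  route is exact and well-behaved with ≥ 5 well-spread r values but is ill
  conditioned for short-modulation options (e.g. a 2–6 g/cm² sweep gives
  only 4–6 distinct r values for 5 coefficients), where measurement noise
  excites large oscillations between samples; validation studies therefore
  use the conversion.

## The virtual machine

`TruthMachine.default()` defines a deterministic ground truth: per option,
a model-B-shaped bare output `K/(1 + a₀* r^{a₁*})·(1 + β*(R − R_max))` with
a₀* ∈ [0.02, 0.06], a₁* ∈ [0.45, 0.60], β* ∈ [0.006, 0.020] spread
deterministically over options, and `K` scaled so the calibration beam
yields exactly 1.06 cGy/MU and the per-option relative outputs span the
realistic 0.79–1.35 range. The a₀*/a₁* windows are chosen so that
piecewise-linear interpolation of the SOBP factor on the standard
modulation grid stays well inside 0.5% — the same design consideration that
motivated the extra 3 g/cm² measurement on the real system. Truth lateral
profiles are asymmetric two-Gaussian bumps (≤ ±2%, widths ≥ 5 cm); the
field-size curve approaches 1 above a 5×5 cm² equivalent with an
exponential small-field falloff and, for the shallowest options (11, 12,
23, 24), a slit-scatter bump that pushes small-field outputs above 1; the
gantry curves are smooth sin² bumps with the per-group amplitudes and peak
angles above. `warped=True` multiplies a ≤ 0.8% smooth perturbation so that
no model under study is exactly true.

`generate_campaign` samples the commissioning design with the exact
published sizes — ROF 24, SOBPF 182, RSF 324, FSF 54 (options 1, 6, 12,
13, 15, 17, 18, 20, 24 × six apertures), GACF 75 (options 3, 5, 17, 18, 20
× 15 angles), plus 24 lateral-profile grids, 72 source-shift points and 272
validation outputs (12 per option for options 1–8, 11 otherwise). The SOBPF
sweep is {2, 3, 4, 6, …} with the terminal modulation appended when it
extends the even grid by more than 0.75 g/cm²; the RSF design measures each
range row up to min(M_max, R), exactly the truncated-row pattern of the
published option-20 grid. Sixty validation points are off-geometry
(|Δz| ∈ [0.5, 3] cm, Δz_p capped at 90% of the effective plateau half-width
M′/2 so the flat-SOBP assumption holds, half also laterally offset up to
4 cm); a quarter of all points use non-zero gantry angles and a fifth a
14 cm circular aperture.

**Noise model.** Multiplicative Gaussian truncated at ±3σ (a reading
further out would be re-measured), σ = 0.5% by default for chamber
readings — σ is a free parameter; the measurement repeatability of the
reference campaign is not published — and 0.1% for the 2-D array's relative
profile (an array acquires the whole profile in one shot, far more
precisely than point-by-point chamber repeatability). Commissioning
measurements at identical physical conditions are drawn once and reused, so
Ψ₀·ROF·SOBPF telescopes to a single measured output exactly as in a real
campaign; validation outputs are always independent draws. One seed drives
the whole campaign; identical seeds reproduce identical campaigns
bit-for-bit.

What the virtual machine does *not* emulate: detector-response and setup
systematics, depth-dose gradient effects for narrow modulations (< 4 g/cm²,
where real plateaus are not flat), beam-current drift, and any correlation
between factors beyond shared readings. Passing tests therefore demonstrate
the correctness and statistical behaviour of the *calculation chain* under
a realistic noise model, not the dosimetric accuracy of any particular
physical machine.

## Validation statistics

Per-point percent difference `(P − M)/M·100`; summaries report mean, sample
SD (n−1), extrema, a 0.5%-bin histogram and the count inside the ±3%
clinical acceptability band. Models evaluated on the same points are
compared with a paired two-sided Student's t-test by default (an unpaired
pooled-variance variant is available); the paired test is checked against
an exact sign-flip permutation oracle in the suite. Note that on synthetic
studies the three models share most of their error (the same tables and
measurements), so paired t-tests can flag tiny systematic differences as
significant even when all models agree with the measurements to well within
tolerance — the p-value compares models with each other, not with truth.

Uncertainty budgets combine per-factor relative uncertainties in
quadrature; the correction model's budget (ROF 0.5, SOBPF 0.5, RSF 1.0,
ISF_OCF 0.5, OCR 1.0, FSF 1.0, GACF 0.5, all %) totals 2.0% for large
fields and 3.46% (~3.5%) when the small-field FSF component rises to 3%.

## Numerical choices and problem sizes

* Interpolation is exact at nodes (verified to 1e-12 against a brute-force
  bilinear oracle); out-of-grid queries raise rather than extrapolate.
* The log-fit placeholder fill requires ≥ 3 measured cells per row.
* Stage-1 fits use bounded TRF least squares, tolerances at machine
  epsilon, five a₀ restarts; quartic fits scale r to [−1, 1] before QR.
* Degenerate inputs: constant modulation sweeps → a₀ = 0 branch (flagged);
  single-range datasets → identity source-shift line; rank-deficient
  quartic designs → error.
* The default test suite and the acceptance script run the full pipeline at
  the published campaign sizes (930 commissioning + 272 validation points
  per replicate); the noisy study uses 20 replicates, which completes in
  about a minute on one CPU — chosen as the point where the replicate SD of
  the validation scatter is estimated to ~2% relative.

## Known limitations

* The per-option range windows below each option's deepest range are not
  published per option; the default catalog uses the maximum in-option
  absorber shift (2.4 g/cm²) clamped at the group minimum, and is meant to
  be edited for a specific machine, as are all ESADs.
* The exact basis of the published placeholder log fit is unrecorded; the
  two-parameter fit reproduces the printed cells to ±0.02 but not exactly
  (the printed shallow-row placeholders are not even monotone in M).
* Model C's direct fit should not be used for options whose commissioned
  modulation span yields fewer than ~8 distinct r values; use the model-B
  conversion.
* FSF interpolation between measured apertures is linear in equivalent
  square; real field-size curves are convex between 5×5 and 10×10 cm², so
  clinical use should measure intermediate apertures rather than trust that
  segment to better than ~1%.
* CSF/PSF (compensator and patient scatter) are out of scope by design —
  the verification-plan workflow cancels them.
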