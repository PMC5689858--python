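# protonmu

Output (cGy/MU) prediction for compact passively double-scattered proton
therapy systems.

Treatment planning systems do not compute reliable monitor units (MU) for
passively scattered proton beams, so clinics need an independent output
calculator: given a beamline *option*, a range `R` (depth of the distal 90%
dose, g/cm²), a modulation width `M` (distal-90% to proximal-95% width), a
collimated field and a gantry angle, predict the dose per monitor unit at
the calibration point and convert the prescribed dose into MU. `protonmu`
implements and cross-validates three interchangeable models for a 24-option
single-room system whose options fall into *large* (1–12), *deep* (13–17)
and *small* (18–24) field types:

**Model A — correction-based.** The measured reference output Ψ₀
(1.06 cGy/MU for the calibration beam: option 20, R 15.0, M 10.0) times
tabulated, independently measured correction factors,

```
Ψ_A = Ψ₀ · ROF · SOBPF · RSF · ISF_OCF · OCR · FSF · GACF
```

with piecewise-linear/bilinear interpolation between measured grid points.
`ISF_OCF = [(ESAD − Δz_p)/(ESAD − Δz_p − Δz)]²` combines the inverse-square
correction for an off-isocenter calibration point with the SOBP off-center
correction (ESAD = effective source-to-axis distance; Δz_p = point offset
from the SOBP center; Δz = SOBP-center-to-isocenter offset).

**Model B — analytical.** A closed form in the SOBP shape variable
`r = (R′ − M′)/M′`, where `R′ = R − 0.31` g/cm² and `M′ = 0.81·M` convert
the vendor definitions to the physical 100%-dose points:

```
Ψ_B = CF · Ψ₀ · D_c · 100/(1 + a₀ r^a₁) · (s₀ + s₁(R − R_L)) · ISF_OCF · OCR · FSF · GACF
```

with option-specific constants `a₀, a₁` (plateau output vs SOBP shape) and
`s₀, s₁` (effective source shift across the option's range window, `R_L`
its lowest range), fitted from the same absolute outputs that build model
A's tables.

**Model C — quartic.** The rational basic term replaced by a quartic
polynomial `p₀ + p₁r + … + p₄r⁴`, obtained most stably as a mathematical
conversion of a fitted model B (`convert_B_to_C`); a direct least-squares
fit to raw outputs (`fit_model_C`) is also provided.

Because no commissioning dataset for such a system is publicly deposited,
the package ships a *virtual machine* (`TruthMachine`) and a campaign
generator that emulate the full measurement effort — 24 relative-output,
182 SOBP-factor, 324 range-shifter, 54 field-size and 75 gantry-angle
measurements, 24 lateral-profile acquisitions and 272 independent
validation outputs — so every model, fitter and statistic is testable end
to end. The printed commissioning excerpts of the reference system (the
relative-output table, three range-shifter grids and nine field-size rows)
are included as `load_published_tables()`.

## Worked example

```python
import protonmu as pm

truth = pm.TruthMachine.default(sigma=0.0)          # noise-free virtual machine
campaign = pm.generate_campaign(truth, sigma=0.0, seed=0)
tables = pm.tables_from_campaign(campaign)

beam = pm.BeamSpec(18, 19.0, 8.0, pm.FieldSize.parse("10x10"), gantry_angle=90.0)
geom = pm.CalibrationGeometry(esad=truth.catalog.get(18).esad, dz_p=0.0, dz=2.0)
pred = pm.predict_output_A(beam, geom, tables)
mu = pm.dose_to_mu(200.0, pred.psi)
```

prints (via `examples/01_predict_output_and_mu.py`):

```
predicted output: 1.1682 cGy/MU
  ROF      1.1200
  SOBPF    0.9921
  RSF      0.9928
  ISF_OCF  1.0232
  OCR      1.0000
  FSF      1.0000
  GACF     0.9764
MU for 200 cGy: 171.20 (delivered as 171.2)
```

The output is the reference 1.06 cGy/MU scaled by option 18's relative
output (1.12), small corrections for this beam's modulation and range, the
inverse-square factor for the 2 cm off-isocenter point, and the
gantry-angle factor at 90°; 200 cGy of planned dose then requires 171.2 MU.
A noisy study (`examples/04_validation_study.py`, 0.5% per-reading noise)
reproduces the character of a real commissioning validation:

```
model A: mean -0.04%  SD 0.83%  range [-2.50, +2.28]%  all/272 within +-3%
model B: mean -0.13%  SD 0.71%  range [-2.59, +1.71]%  all/272 within +-3%
model C: mean -0.14%  SD 0.71%  range [-2.62, +1.60]%  all/272 within +-3%
```

The other examples cover the published tables (`02`), analytical-model
fitting and the quartic conversion (`03`), and the uncertainty budget
(`05`). A thin command line (`protonmu catalog|tables|predict|simulate|
fit|validate`) wraps the same calls for shell use.

## Documentation

`docs/methods.md` describes the models, the virtual machine and its noise
model, the fitting procedures, numerical choices and known limitations.
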