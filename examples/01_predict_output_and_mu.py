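"""Predict the output of one beam and convert a prescription dose to MU.

Builds noise-free commissioning tables from the virtual machine, then
predicts the output for a small-applicator beam whose calibration point sits
2 cm proximal of the isocenter, and converts a 200 cGy verification-plan
dose into monitor units.
"""

import protonmu as pm

truth = pm.TruthMachine.default(sigma=0.0)
campaign = pm.generate_campaign(truth, sigma=0.0, seed=0)
tables = pm.tables_from_campaign(campaign)

beam = pm.BeamSpec(18, 19.0, 8.0, pm.FieldSize.parse("10x10"), gantry_angle=90.0)
pm.validate_beam(beam, truth.catalog)
geom = pm.CalibrationGeometry(esad=truth.catalog.get(18).esad, dz_p=0.0, dz=2.0)

pred = pm.predict_output_A(beam, geom, tables)
print(f"predicted output: {pred.psi:.4f} cGy/MU")
for name, value in pred.factors.items():
    print(f"  {name:<8} {value:.4f}")

mu = pm.dose_to_mu(200.0, pred.psi)
print(f"MU for 200 cGy: {mu.mu:.2f} (delivered as {mu.mu_rounded:g})")
# The factor breakdown multiplies psi_o (1.06 cGy/MU) into the prediction:
# ROF scales between options, SOBPF/RSF for this beam's modulation and range,
# ISF_OCF for the 2 cm off-isocenter point, and GACF for the 90-degree gantry.
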