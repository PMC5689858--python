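"""Combine per-factor uncertainties into a model's total uncertainty.

Each correction factor carries an estimated relative uncertainty; because
the factors multiply, the relative uncertainties combine in quadrature.
Small apertures (at or below 5x5 cm2) raise the field-size component to 3%,
which is why their outputs should be measured directly.
"""

import protonmu as pm

components = {
    "ROF": 0.5, "SOBPF": 0.5, "RSF": 1.0, "ISF_OCF": 0.5,
    "OCR": 1.0, "FSF": 1.0, "GACF": 0.5,
}
large = pm.propagate_uncertainty(components)
print("correction model, large field:")
for name, v in large.components.items():
    print(f"  {name:<8} {v:.1f}%")
print(f"  total    {large.total:.1f}%  (quadrature sum)")

small = pm.propagate_uncertainty(dict(components, FSF=3.0))
print(f"\nsmall field (FSF 3.0%): total {small.total:.3f}% (~{small.total:.1f}%)")
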