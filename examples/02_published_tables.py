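"""Work with the published commissioning excerpts shipped with the package.

Looks up printed relative-output and field-size factors, interpolates the
range-shifter grid between printed rows, and refits the log-law extrapolation
for the cells that cannot be measured because the modulation would exceed
the range.
"""

import numpy as np

import protonmu as pm

tables = pm.load_published_tables()

print(f"reference output: {tables.psi_o} cGy/MU (option 20, R 15.0, M 10.0)")
print(f"ROF option 13 (deepest beam): {tables.lookup_rof(13)}")
print(f"ROF option 1:  {tables.lookup_rof(1)}")

# bilinear interpolation between printed rows of the range-shifter grid
v = tables.interp_rsf(1, 24.4, 10.0)
print(f"RSF option 1 at R 24.4, M 10: {v:.5f} (midway between 1.0000 and 0.9931)")

# field-size factors interleave square and circular apertures via the
# equivalent-square convention
fsf = tables.interp_fsf(1, pm.FieldSize.parse("3.5d"))
print(f"FSF option 1 for a 3.5 cm circle: {fsf} (small fields lose scatter)")

# refit the placeholder cells of the shallow-range row and compare
grid = tables.rsf[20]
printed = grid.values[0, 3:5].copy()
grid.values[grid.placeholder] = np.nan
grid.placeholder[:] = False
tables.fill_rsf_placeholders(20)
print("option 20 extrapolated cells (refit vs printed):",
      np.round(grid.values[0, 3:5], 4), "vs", printed)
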