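"""Walk the conversion chain on the packaged reference table.

Calibrates the abundance-to-concentration constant K on the actin row,
then reproduces the other proteins' cellular concentrations and copy
numbers from their blot abundances and molecular weights.
"""

from abpcensus import (
    abundance_to_concentration,
    concentration_to_molecules,
    cytosolic_volume,
    default_constants,
    load_reference_table,
)

constants = default_constants()  # K calibrated on the actin row
volume = cytosolic_volume(constants)
print(f"conversion constant K = {constants.conversion_k:.2f} µM·kDa/(ng/µg)")
print(f"cytosolic volume      = {volume:.1f} fL\n")

print(f"{'protein':8s} {'ng/µg':>6s} {'µM (derived)':>12s} {'µM (published)':>14s} {'molecules':>10s}")
for r in load_reference_table():
    conc = abundance_to_concentration(r.abundance, r.mw, constants)
    n = concentration_to_molecules(conc, volume)
    print(f"{r.name:8s} {r.abundance:6.2f} {conc:12.2f} {r.cellular_conc:14.2f} {n:10.0f}")

# The derived µM column matches the published one because both follow the
# same calibrated chain; molecules/cell are concentration x volume x N_A.
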