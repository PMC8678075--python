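"""Worked example: why the two-compartment model overestimates Texch.

Simulates a noise-free multi-TE ASL signal with the extended three-component
model (ITT = 200 ms, Texch = 150 ms, ATT = 500 ms, bolus 1,800 ms) on a dense
TI grid at the eight study echo times, then fits it with both models.
"""

import json

from mteasl.replicate import worked_example_study

res = worked_example_study()
print(json.dumps({k: round(v, 1) for k, v in res.items()}, indent=2))
print()
print(f"True exchange time          : {res['texch_true']:.0f} ms")
print(f"Extended model estimate     : {res['texch_extended']:.1f} ms")
print(f"Two-compartment estimate    : {res['texch_2cm']:.1f} ms "
      f"({res['texch_2cm_pct_dev']:+.0f} %)")
print()
print("The extended model recovers the simulated exchange time exactly;")
print("the two-compartment model, lacking the intra-voxel transit stage,")
print("absorbs part of the transit delay into an inflated exchange time.")
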