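"""Small-scale error-surface study: the cost of ignoring intra-voxel transit.

Runs the grid study (ATT 500-2,500 ms x Texch 10-1,000 ms, ITT 200 ms,
perfusion 60 ml/100 g/min) at 6 x 6 desk scale, fits both models and prints
the deviation statistics plus the identity-line offsets for different
simulated ITT values.  Takes about a minute on one CPU; raise the grid size
for smoother surfaces.
"""

import json

from mteasl.replicate import error_surface_study

summary = error_surface_study(n_att=6, n_texch=6, itt_values=(0.0, 200.0, 400.0))
print(json.dumps(summary, indent=2))
print()
two = summary["two_compartment"]
print(f"Two-compartment Texch error, mean over true Texch < 300 ms : "
      f"{two['texch_pct_dev_mean_low']:+.0f} %")
print(f"Two-compartment Texch error, mean over true Texch > 500 ms : "
      f"{two['texch_pct_dev_mean_high']:+.0f} %")
print("Identity-line offset (ms) by simulated ITT:",
      summary["identity_offset_by_itt"])
print()
print("Fast exchange (low Texch) is hit hardest by the missing transit")
print("stage, and the offset grows with the simulated intra-voxel transit")
print("time; the extended model recovers every parameter to within a")
print("fraction of a percent on noise-free data.")
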