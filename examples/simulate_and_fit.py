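"""Simulate a small parameter-grid phantom and map all four parameters.

A 4 x 4 grid spans arterial transit times 600-2,000 ms and exchange times
100-600 ms (ITT fixed at 200 ms, perfusion 60 ml/100 g/min).  The decoded
multi-TE dataset over both study protocols is fitted voxel-wise with the
extended model and the perfusion amplitude is calibrated to CBF.
"""

import numpy as np

from mteasl import (
    PhantomSpec,
    TissueConstants,
    fit_volume,
    make_phantom,
    percent_deviation,
    quantify_cbf,
    simulate_dataset,
)
from mteasl.encoding import study_protocols

constants = TissueConstants()
protocols = study_protocols()
schemes = [acq for _, acq in protocols]

truth = make_phantom(PhantomSpec(shape=(4, 4, 1), att_range=(600.0, 2000.0),
                                 texch_range=(100.0, 600.0), itt=200.0))
series, _ = simulate_dataset(truth, protocols, constants)
maps = fit_volume(series, None, "extended", schemes, constants)

cbf = quantify_cbf(maps.cbf, constants.partition_coeff * truth.m0, constants)
dev = percent_deviation(maps.texch, truth.texch)

print("true Texch (ms), one row per ATT:")
print(np.round(truth.texch[:, :, 0], 0))
print("fitted Texch (ms):")
print(np.round(maps.texch[:, :, 0], 1))
print(f"max |Texch deviation|: {np.nanmax(np.abs(dev)):.2f} %")
print(f"CBF recovered: {np.nanmin(cbf):.2f}-{np.nanmax(cbf):.2f} ml/100 g/min "
      "(truth 60)")
print(f"max ITT error: {np.nanmax(np.abs(maps.itt - truth.itt)):.1f} ms")
print("\nNoise-free recovery is essentially exact: the multi-TE sampling")
print("separates transit, exchange and perfusion.")
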