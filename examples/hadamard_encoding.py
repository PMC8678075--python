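"""Hadamard time-encoding: protocol construction, decoding and noise gain.

Builds the two study protocols, shows the decoded inflow times, verifies the
encode/decode round trip and measures the noise-averaging benefit of the
Hadamard-8 scheme on synthetic white noise.
"""

import numpy as np
import pandas as pd

from mteasl.encoding import build_protocol, decode, encode
from mteasl.types import EncodedSeries

had8, acq8 = build_protocol(8, sbd=400.0, pld=200.0)
had4, acq4 = build_protocol(4, sbd=1000.0, pld=600.0)
print("Protocol 1 (Hadamard-8, SBD 400 ms, PLD 200 ms) TIs:", acq8.ti_list)
print("Protocol 2 (Hadamard-4, SBD 1000 ms, PLD 600 ms) TIs:", acq4.ti_list)

rng = np.random.default_rng(0)
pwis = rng.random((4, 4, 1, 7, 8))
enc = encode(pwis, static=100.0, scheme=had8, te_list=acq8.te)
rec = decode(enc, had8).volumes.reshape(pwis.shape)
print(f"\nencode -> decode round-trip error: {np.abs(rec - pwis).max():.2e}")

noise = EncodedSeries(
    volumes=rng.standard_normal((50_000, 1, 1, 8)),
    frame_meta=pd.DataFrame({"row": np.arange(8), "te": np.zeros(8)}),
)
var = decode(noise, had8).volumes.var()
print(f"decoded noise variance for unit input variance: {var:.3f} "
      "(theory: 4/order = 0.5)")
print("\nDecoding averages all acquisitions per perfusion-weighted image,")
print("halving the white-noise variance relative to simple pair subtraction.")
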