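"""Test-retest reliability statistics on a synthetic ten-subject study.

Generates grey-matter mean exchange times for ten subjects measured in two
sessions (between-subject SD 38 ms around 228 ms; within-subject SD chosen
for a 7 % within-subject CoV) and reports ICC(2,1), wsCoV with a bootstrap
interval, and Bland-Altman limits of agreement.
"""

import numpy as np

from mteasl.stats import (
    bland_altman,
    icc,
    within_subject_cov,
    wscov_bootstrap_ci,
)

rng = np.random.default_rng(42)
mu, between_sd, target_cov = 228.0, 38.0, 7.0
ws_sd = target_cov / 100.0 * mu

subjects = rng.normal(mu, between_sd, 10)
sessions = subjects[:, None] + rng.normal(0.0, ws_sd, (10, 2))

icc_val, icc_p = icc(sessions)
cov = within_subject_cov(sessions)
lo, hi = wscov_bootstrap_ci(sessions, seed=0)
ba = bland_altman(sessions)

print(f"ICC(2,1)            : {icc_val:.3f} (p = {icc_p:.4f})")
print(f"within-subject CoV  : {cov:.1f} %  (99 % bootstrap CI "
      f"{lo:.1f}-{hi:.1f} %; generating value {target_cov:.0f} %)")
print(f"Bland-Altman        : mean diff {ba['mean_diff']:+.1f} ms, "
      f"limits [{ba['loa_low']:+.1f}, {ba['loa_high']:+.1f}] ms")
print()
print("A CoV in the single digits with a significant ICC indicates the")
print("exchange-time measurement is reproducible across repeated sessions.")
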