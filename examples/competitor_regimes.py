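"""Competitor interplay: transcription rate vs binding strength of target 2.

Raising either the competitor's transcription rate (k_r2) or its binding
strength (g_2) sequesters miRNA away from target 1 and moves its threshold
to lower constitutive levels.  The two knobs are not equivalent in the
strong-binding limit: if alpha*k_r2 exceeds the miRNA supply k_s the limit
is the unregulated line, otherwise a residual threshold survives.
"""

import numpy as np
from dataclasses import replace

from mircrosstalk import (
    limiting_curve_g2_inf,
    reference_params,
    sweep_competitor,
    sweep_p0,
    unregulated_sweep,
)

fine = np.geomspace(2, 500, 120)
base = replace(reference_params(), g_2=0.3)

family = sweep_competitor(base, "k_r2", np.array([2.0, 4.0, 6.0, 10.0]), fine)
print("threshold p0* vs competitor transcription rate (sponging regime):")
for v, sw in family.items():
    print(f"  k_r2 = {v:4.0f} -> p0* = {sw.threshold().p0_star:7.1f}")

print("\nthreshold p0* vs competitor binding strength:")
for g2 in [0.0, 0.3, 1.0]:
    t = sweep_p0(replace(reference_params(), g_2=g2), fine).threshold()
    print(f"  g_2 = {g2:4.2f} -> p0* = {t.p0_star:7.1f}")

grid = np.geomspace(2, 500, 40)
un = unregulated_sweep(reference_params(), grid)
for k_r2, label in [(30.0, "alpha*k_r2 > k_s (excess targets)"),
                    (6.0, "alpha*k_r2 < k_s (excess miRNA)")]:
    lim = limiting_curve_g2_inf(replace(reference_params(), k_r2=k_r2), grid)
    dev = np.max(np.abs(lim.mean_p1 / un.mean_p1 - 1))
    slope = lim.threshold().max_slope
    print(f"\ng_2 -> infinity with {label}:")
    print(f"  max deviation from the unregulated line: {dev:.2f}; "
          f"max log-log slope {slope:.2f}"
          f" ({'threshold survives' if slope > 1.05 else 'regulation gone'})")
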