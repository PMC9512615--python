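"""Compare the four shrinkage (thresholding) functions on one coefficient axis.

Hard thresholding keeps coefficients above the threshold untouched, soft
shrinks them by the full threshold, and the compromise/improved variants
interpolate via the adjustment coefficient a; the improved rule also
attenuates (rather than zeroes) sub-threshold coefficients, retaining weak
signal detail.
"""

import numpy as np

from ctdenoise import ShrinkageRule, shrink

lam = 1.0
ws = np.array([-2.0, -1.2, -0.5, 0.0, 0.5, 1.2, 2.0])
rules = {
    "hard": ShrinkageRule("hard"),
    "soft": ShrinkageRule("soft"),
    "compromise a=0.5": ShrinkageRule("compromise", a=0.5),
    "improved a=0.5": ShrinkageRule("improved", a=0.5),
}
print(f"threshold lambda = {lam}")
print(f"{'w':>18s}" + "".join(f"{w:8.2f}" for w in ws))
for name, rule in rules.items():
    out = shrink(ws, lam, rule)
    print(f"{name:>18s}" + "".join(f"{v:8.2f}" for v in out))
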