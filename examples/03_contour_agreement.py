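"""Score contour agreement with DSC and compare two methods by Wilcoxon.

Builds two overlapping toy masks and prints their Dice similarity, then
simulates per-case DSC scores of two segmentation methods across organs
and prints the Tables-style summary: per-organ means for both methods,
the paired Wilcoxon signed-rank p-value, and the 0.80-acceptability flag.
"""

import numpy as np
import pandas as pd

from atvseg import BinaryMask, dice, dsc_table, paired_wilcoxon

# --- a single DSC -----------------------------------------------------------
a = np.zeros((4, 16, 16), bool)
b = np.zeros((4, 16, 16), bool)
a[1:3, 4:12, 4:12] = True       # "manual" contour
b[1:3, 5:13, 4:12] = True       # shifted "automatic" contour
result = dice(BinaryMask(a, "heart"), BinaryMask(b, "heart"))
print(f"DSC(heart) = {result.value:.3f}  "
      f"(|A|={result.volume_a}, |B|={result.volume_b}, "
      f"|A n B|={result.volume_intersection}; 1.0 = complete overlap)")

# --- a paired comparison across cases --------------------------------------
rng = np.random.default_rng(7)
rows = []
for organ, base, benefit in [("liver", 0.92, 0.015), ("esophagus", 0.70, 0.0)]:
    for case in range(12):
        ref = np.clip(base + rng.normal(0, 0.02), 0, 1)
        rows.append({"case": f"c{case}", "organ": organ,
                     "method": "no_denoiser", "dsc": ref})
        rows.append({"case": f"c{case}", "organ": organ,
                     "method": "denoised",
                     "dsc": np.clip(ref + benefit + rng.normal(0, 0.005), 0, 1)})

summary = dsc_table(pd.DataFrame(rows)).summary
print("\nper-organ summary (mean DSC per method, Wilcoxon p, acceptable at 0.80):")
print(summary.round(4).to_string())
print("\n(a p-value < 0.05 marks a statistically significant DSC difference "
      "between the methods; here the liver improves, the esophagus does not)")

# --- the exact small-sample path -------------------------------------------
res = paired_wilcoxon(np.arange(1.0, 7.0), np.zeros(6))
print(f"\nexact Wilcoxon, n=6, all differences positive: "
      f"p = {res.p_value:.5f} (= 2/2^6)")
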