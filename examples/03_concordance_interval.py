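"""Exact binomial confidence intervals for concordant positivity calls.

With 63 subjects, 53 concordant temporal-composite calls and 59 concordant
cortical-composite calls give the intervals below; Clopper-Pearson bounds
come from beta-distribution quantiles, so they are exact at any n.
"""

from tauconcord.stats import clopper_pearson

for label, k in (("temporal", 53), ("cortical", 59)):
    low, high = clopper_pearson(k, 63)
    print(f"{label}: {k}/63 concordant -> accuracy {k / 63:.3f} "
          f"(95% CI {low:.3f}-{high:.3f})")
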