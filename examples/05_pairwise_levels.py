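"""A three-level factor handled as all pairwise two-sample screens.

A feature that only distinguishes one pair of levels still surfaces in the
union of per-pair selections — the overall biomarker candidate set.
"""

import numpy as np

from mor import pairwise_levels

rng = np.random.default_rng(9)
group = np.repeat(["sham", "low_dose", "high_dose"], 12)
f0 = rng.standard_normal(36) * 0.4
f0[group == "high_dose"] += 3.0          # responds to the high dose only
f1 = np.tile(np.arange(12.0), 3)          # identical in every level
values = np.column_stack([f0, f1])

res = pairwise_levels(values, group, feature_names=["marker", "flat"])
for (a, b), (chain, sel) in res.pairs.items():
    print(f"{a} vs {b}: selected = {sel.selected}")
print("overall candidates:", res.union)

# 'marker' is picked up by both comparisons involving the high-dose level
# and absent from sham-vs-low; the union declares it an overall candidate.
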