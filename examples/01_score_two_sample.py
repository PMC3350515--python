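"""Score a small two-sample table and read the information chain.

Builds a 20-sample study with six features — one of which separates the two
groups completely — scores every feature with the Measure of Relevance
(MoR = c * |O| * B / S on pooled-rank/U-transformed data) and prints the
information chain.
"""

import numpy as np

from mor import FeatureMatrix, build_chain, score_features

rng = np.random.default_rng(1)
values = rng.standard_normal((20, 6))
values[:, 5] = np.concatenate([np.arange(10, 20), np.arange(10)])  # separated

matrix = FeatureMatrix(values=values, group=np.array(["case"] * 10 + ["control"] * 10))
chain = build_chain(score_features(matrix))
print(chain[["B", "S", "O", "mor", "chain_rank"]].round(4))

# The separated feature f5 attains the maximal biological difference B = 0.5
# and the overlap factor's ceiling, giving MoR = 15.57; the noise features
# sit an order of magnitude lower.  Large |MoR| marks biomarker candidates,
# the sign gives the direction (group 1 minus group 2).
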