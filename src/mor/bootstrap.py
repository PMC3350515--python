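"""Percentile bootstrap confidence intervals for per-feature MoR values.

Resampling respects the sampling design: independent groups are resampled
with replacement within each group, matched samples are resampled as whole
pairs (the dependent MoR formulas need the pairing intact).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import FeatureMatrix
from .relevance import score_features

__all__ = ["bootstrap_ci"]


def bootstrap_ci(
    matrix: FeatureMatrix,
    features: list[str] | None = None,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    gamma: float = 0.5,
    c: float = 1.0,
    mode: str = "rank",
) -> pd.DataFrame:
    """Percentile interval of MoR per feature over ``n_boot`` resamples.

    Returns a DataFrame (feature, mor, lower, upper) at the given coverage
    ``level``.  ``features`` restricts the report (all scored features by
    default); the point estimate is the MoR of the original sample.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    kw = dict(gamma=gamma, c=c, mode=mode)
    point = score_features(matrix, **kw)
    names = list(point.index) if features is None else list(features)
    cols = [list(point.index).index(f) for f in names]

    g1, g2 = matrix.group_masks()
    idx1 = np.flatnonzero(g1)
    idx2 = np.flatnonzero(g2)
    dep = matrix.design == "dependent"
    if dep:
        # align pair order so row i of each block is one pair
        idx1 = idx1[np.argsort(matrix.pair_id[idx1], kind="stable")]
        idx2 = idx2[np.argsort(matrix.pair_id[idx2], kind="stable")]

    boot = np.empty((n_boot, len(cols)))
    for b in range(n_boot):
        if dep:
            take = rng.integers(0, len(idx1), size=len(idx1))
            rows1, rows2 = idx1[take], idx2[take]
            pair = np.concatenate([np.arange(len(take))] * 2)
        else:
            rows1 = rng.choice(idx1, size=len(idx1), replace=True)
            rows2 = rng.choice(idx2, size=len(idx2), replace=True)
            pair = None
        values = np.vstack([matrix.values[rows1], matrix.values[rows2]])
        group = np.concatenate([matrix.group[rows1], matrix.group[rows2]])
        bm = FeatureMatrix(
            values=values, group=group, design=matrix.design, pair_id=pair,
            feature_names=list(matrix.feature_names),
            feature_kind=list(matrix.feature_kind),
        )
        boot[b] = score_features(bm, **kw)["mor"].to_numpy()[cols]

    lo = (1.0 - level) / 2.0
    return pd.DataFrame(
        {
            "mor": point["mor"].to_numpy()[cols],
            "lower": np.quantile(boot, lo, axis=0),
            "upper": np.quantile(boot, 1.0 - lo, axis=0),
        },
        index=pd.Index(names, name="feature"),
    )
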