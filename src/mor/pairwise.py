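"""Multi-level factors: all pairwise two-sample analyses.

A factor with k > 2 levels is handled by running the full two-sample
screening on every one of the k(k-1)/2 level pairs and declaring the union
of the per-pair selections the overall biomarker candidates — each pair is
exactly the two-sample problem the MoR is built for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .data import FeatureMatrix, infer_feature_kinds
from .selection import SelectionResult, screen

__all__ = ["PairwiseResult", "pairwise_levels"]


@dataclass
class PairwiseResult:
    """Per-level-pair screenings plus the union of candidates."""

    pairs: dict = field(default_factory=dict)  # (level_a, level_b) -> (chain, SelectionResult)
    union: list[str] = field(default_factory=list)

    def selection(self, level_a, level_b) -> SelectionResult:
        return self.pairs[(level_a, level_b)][1]


def pairwise_levels(
    values: np.ndarray | pd.DataFrame,
    group: np.ndarray,
    feature_names: list[str] | None = None,
    **screen_kwargs,
) -> PairwiseResult:
    """Screen every pair of levels of a k-level group factor.

    ``values`` is samples-by-features (DataFrame columns give feature names),
    ``group`` the k-level label vector.  Each level pair is analysed as an
    independent two-sample problem via :func:`mor.selection.screen`;
    ``screen_kwargs`` are forwarded (w, z0, refine, ...).  The union of the
    per-pair selections, in first-seen order, is the overall candidate set.
    Two levels degenerate to the single standard analysis.
    """
    if isinstance(values, pd.DataFrame):
        feature_names = feature_names or list(values.columns)
        values = values.to_numpy(dtype=float)
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    levels = list(pd.unique(group[~pd.isna(group)]))
    if len(levels) < 2:
        raise ValueError("need at least two group levels")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(values.shape[1])]

    result = PairwiseResult()
    seen: dict[str, None] = {}
    for a, b in combinations(levels, 2):
        mask = (group == a) | (group == b)
        sub = FeatureMatrix(
            values=values[mask],
            group=group[mask],
            design="independent",
            feature_names=list(feature_names),
            feature_kind=infer_feature_kinds(
                pd.DataFrame(values[mask], columns=feature_names)
            ),
        )
        chain, sel = screen(sub, **screen_kwargs)
        result.pairs[(a, b)] = (chain, sel)
        for f in sel.selected:
            seen.setdefault(f)
    result.union = list(seen)
    return result
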