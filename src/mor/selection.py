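"""Selection criteria: how far down the information chain features count.

Four criterion families decide which chain members are relevant biomarker
candidates:

* **entropy** — grow the chain prefix until the relative gain in Shannon
  entropy of the |MoR|-proportional weights becomes negligible (< delta);
  suited to very small samples.
* **permutation** — compare each observed |MoR| with its null distribution
  under random re-assignment of the group labels (exhaustive when feasible);
  suited to moderate samples, computationally heavy.
* **fraction / top_proportion** — subjective cut-offs: the shortest prefix
  carrying a given share of total |MoR|, or the top ceil(eps * p) features.
* **sample_cutoff** — the objective, sample-size-related threshold
  |MoR| >= w * Z0 / sqrt(n1 + n2) with Z0 ~ 3.28 (two 5% standard-normal
  tail quantiles); shrinks as samples grow, so it is the natural first
  screen for larger studies.

``screen`` chains the objective cut-off with an optional subjective
refinement, reporting explicitly when no feature clears the bar.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .data import FeatureMatrix
from .relevance import build_chain, score_features

__all__ = [
    "SelectionResult",
    "entropy_criterion",
    "permutation_criterion",
    "fraction_cutoff",
    "top_proportion_cutoff",
    "sample_cutoff",
    "screen",
    "Z0_DEFAULT",
]

#: sum of the two one-sided 5% standard-normal tail quantiles, 2 * 1.6449
Z0_DEFAULT = 3.28


@dataclass
class SelectionResult:
    """Outcome of one selection criterion.

    ``selected`` lists feature names in chain order; ``decisions`` is a
    per-feature boolean Series over all scored features; ``threshold`` is the
    criterion's cut value (scalar, or per-feature Series for sample_cutoff).
    """

    criterion: str
    parameters: dict = field(default_factory=dict)
    threshold: object = None
    selected: list[str] = field(default_factory=list)
    decisions: pd.Series | None = None
    status: str = "ok"

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    def to_dict(self) -> dict:
        thr = self.threshold
        if isinstance(thr, pd.Series):
            thr = {k: float(v) for k, v in thr.items()}
        elif thr is not None:
            thr = float(thr)
        return {
            "criterion": self.criterion,
            "parameters": self.parameters,
            "threshold": thr,
            "selected": list(self.selected),
            "status": self.status,
        }


def _prefix_result(chain: pd.DataFrame, k: int, criterion: str, params: dict,
                   threshold=None, status: str = "ok") -> SelectionResult:
    selected = list(chain.index[:k])
    decisions = pd.Series(False, index=chain.index.sort_values())
    decisions.loc[selected] = True
    # report decisions in original score order where possible
    decisions = decisions.reindex(chain.sort_values("chain_rank").index)
    return SelectionResult(criterion, params, threshold, selected, decisions, status)


def prefix_entropy(abs_mor: np.ndarray) -> np.ndarray:
    """Shannon entropy H_k of |MoR|-proportional weights for every prefix k.

    For prefix size k the weights are q_i = |mor_(i)| / sum_{j<=k} |mor_(j)|
    and H_k = -sum q_i ln q_i.  Equal |mor| values give H_k = ln k exactly.
    """
    abs_mor = np.asarray(abs_mor, dtype=float)
    h = np.empty(len(abs_mor))
    for k in range(1, len(abs_mor) + 1):
        w = abs_mor[:k]
        tot = w.sum()
        if tot <= 0:
            h[k - 1] = 0.0
            continue
        q = w[w > 0] / tot
        h[k - 1] = float(-(q * np.log(q)).sum())
    return h


def entropy_criterion(
    chain: pd.DataFrame,
    delta: float = 0.01,
    change: Literal["relative", "absolute"] = "relative",
) -> SelectionResult:
    """Stop extending the chain prefix once the entropy gain is negligible.

    With H_k the prefix entropy, the adjusted change of entropy when adding
    member k+1 is D_k = (H_{k+1} - H_k)/H_k (``change="absolute"`` drops the
    normalization).  The selected prefix is the smallest k (>= 2) at which
    D_k < delta first holds; if the condition never triggers, all features
    with |mor| > 0 are selected.  An all-zero chain selects nothing.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    params = {"delta": delta, "change": change}
    if len(chain) == 0:
        return _prefix_result(chain, 0, "entropy", params)
    abs_mor = np.abs(chain["mor"].to_numpy())
    nonzero = int(np.sum(abs_mor > 0))
    if nonzero == 0:
        return _prefix_result(chain, 0, "entropy", params, status="none_informative")
    h = prefix_entropy(abs_mor)
    k_star = nonzero  # fallback: never-negligible growth
    for k in range(2, len(chain)):
        if h[k - 1] <= 0:
            k_star = k
            break
        d_k = h[k] - h[k - 1]
        if change == "relative":
            d_k /= h[k - 1]
        if d_k < delta:
            k_star = k
            break
    k_star = max(1, min(k_star, nonzero))
    return _prefix_result(chain, k_star, "entropy", params, threshold=delta)


def _permute_independent(rng: np.random.Generator, n: int, n1: int, n_perm: int):
    """Yield boolean group-1 masks: exhaustive if C(n, n1) <= n_perm, else random."""
    total = math.comb(n, n1)
    if total <= n_perm:
        for idx in itertools.combinations(range(n), n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            yield mask
    else:
        for _ in range(n_perm):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=n1, replace=False)] = True
            yield mask


def _permute_dependent(rng: np.random.Generator, n_pairs: int, n_perm: int):
    """Yield sign-flip vectors (+1 keeps the pair, -1 swaps within the pair)."""
    if 2 ** n_pairs <= n_perm:
        for bits in itertools.product((1.0, -1.0), repeat=n_pairs):
            yield np.array(bits)
    else:
        for _ in range(n_perm):
            yield rng.choice((1.0, -1.0), size=n_pairs)


def permutation_criterion(
    matrix: FeatureMatrix,
    alpha: float = 0.05,
    n_perm: int = 1000,
    top_m: int | None = None,
    seed: int | None = None,
    gamma: float = 0.5,
    c: float = 1.0,
    mode: Literal["rank", "raw"] = "rank",
) -> SelectionResult:
    """Per-feature permutation test on |MoR|.

    The group variable is permuted (independent design: labels reshuffled at
    fixed n1, n2; dependent design: members swapped within pairs) and the
    MoR recomputed each time.  A feature is relevant when its observed |MoR|
    sits among the alpha-fraction greatest permutation values, i.e. its
    permutation p-value #{|MoR*| >= |MoR|}/K is <= alpha.  When the number
    of distinct permutations is at most ``n_perm`` they are enumerated
    exhaustively (the observed assignment is then one of them).  ``top_m``
    restricts testing to the first chain members; untested features are
    reported unselected.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    kw = dict(gamma=gamma, c=c, mode=mode)
    scores = score_features(matrix, **kw)
    chain = build_chain(scores)
    tested = list(chain.index[:top_m]) if top_m else list(scores.index)
    tested_set = set(tested)
    cols = [j for j, nme in enumerate(scores.index) if nme in tested_set]
    obs = np.abs(scores["mor"].to_numpy())[cols]

    if matrix.design == "independent":
        g1_mask, _ = matrix.group_masks()
        n1 = int(g1_mask.sum())
        n = matrix.n_samples
        lvl1, lvl2 = matrix.group_levels
        exhaustive = math.comb(n, n1) <= n_perm
        perms = _permute_independent(rng, n, n1, n_perm)

        def permuted_scores(mask):
            grp = np.where(mask, lvl1, lvl2)
            pm = FeatureMatrix(
                values=matrix.values, group=grp, design="independent",
                feature_names=matrix.feature_names, feature_kind=matrix.feature_kind,
            )
            return np.abs(score_features(pm, **kw)["mor"].to_numpy())[cols]
    else:
        v1, v2 = matrix.group_values()
        n_pairs = v1.shape[0]
        lvl1, lvl2 = matrix.group_levels
        exhaustive = 2 ** n_pairs <= n_perm
        perms = _permute_dependent(rng, n_pairs, n_perm)

        def permuted_scores(signs):
            swap = signs < 0
            w1 = np.where(swap[:, None], v2, v1)
            w2 = np.where(swap[:, None], v1, v2)
            pm = FeatureMatrix(
                values=np.vstack([w1, w2]),
                group=np.array([lvl1] * n_pairs + [lvl2] * n_pairs),
                design="dependent",
                pair_id=np.concatenate([np.arange(n_pairs)] * 2),
                feature_names=matrix.feature_names,
                feature_kind=matrix.feature_kind,
            )
            return np.abs(score_features(pm, **kw)["mor"].to_numpy())[cols]

    null = np.array([permuted_scores(p) for p in perms])
    k_used = null.shape[0]
    n_ge = (null >= obs[None, :] - 1e-12).sum(axis=0)
    pvals = n_ge / k_used
    sel = pvals <= alpha

    decisions = pd.Series(False, index=scores.index)
    decisions.iloc[cols] = sel
    selected = [f for f in chain.index if decisions.get(f, False)]
    return SelectionResult(
        "permutation",
        {"alpha": alpha, "n_perm": k_used, "top_m": top_m, "seed": seed,
         "exhaustive": exhaustive},
        None,
        selected,
        decisions,
    )


def fraction_cutoff(chain: pd.DataFrame, d: float) -> SelectionResult:
    """Shortest prefix carrying at least a fraction ``d`` of total |MoR|."""
    if not 0 < d <= 1:
        raise ValueError("d must lie in (0, 1]")
    abs_mor = np.abs(chain["mor"].to_numpy())
    total = abs_mor.sum()
    params = {"d": d}
    if total == 0:
        return _prefix_result(chain, 0, "fraction", params, status="none_informative")
    cum = np.cumsum(abs_mor) / total
    k = int(np.searchsorted(cum, d - 1e-12) + 1)
    k = min(k, int(np.sum(abs_mor > 0)))
    return _prefix_result(chain, k, "fraction", params, threshold=d)


def top_proportion_cutoff(chain: pd.DataFrame, epsilon: float) -> SelectionResult:
    """The ceil(epsilon * p) features with the largest |MoR|."""
    if not 0 <= epsilon <= 1:
        raise ValueError("epsilon must lie in [0, 1]")
    k = math.ceil(epsilon * len(chain))
    return _prefix_result(chain, k, "top_proportion", {"epsilon": epsilon}, threshold=epsilon)


def sample_cutoff(
    scores: pd.DataFrame, w: float = 1.0, z0: float = Z0_DEFAULT
) -> SelectionResult:
    """Objective sample-size-related cut-off: |MoR| >= w * Z0 / sqrt(n1 + n2).

    ``w`` weights the desired effect magnitude (braking factor: larger w,
    stricter screen); the threshold uses each feature's own non-missing
    counts, so it shrinks as information accrues.
    """
    if w <= 0 or z0 <= 0:
        raise ValueError("w and z0 must be positive")
    n_tot = scores["n1"].to_numpy() + scores["n2"].to_numpy()
    with np.errstate(divide="ignore"):
        thr = np.where(n_tot > 0, w * z0 / np.sqrt(np.maximum(n_tot, 1)), np.inf)
    decisions = pd.Series(np.abs(scores["mor"].to_numpy()) >= thr, index=scores.index)
    chain = build_chain(scores)
    selected = [f for f in chain.index if decisions[f]]
    status = "ok" if selected else "none_informative"
    return SelectionResult(
        "sample_cutoff",
        {"w": w, "z0": z0},
        pd.Series(thr, index=scores.index),
        selected,
        decisions,
        status,
    )


def screen(
    matrix: FeatureMatrix,
    w: float = 1.0,
    z0: float = Z0_DEFAULT,
    refine: Literal["fraction", "top_proportion", "entropy", None] = None,
    refine_param: float | None = None,
    gamma: float = 0.5,
    c: float = 1.0,
    mode: Literal["rank", "raw"] = "rank",
) -> tuple[pd.DataFrame, SelectionResult]:
    """Objective-first screening workflow.

    Scores all features, applies the sample-related cut-off, and — when it
    passes too many candidates for practical follow-up — optionally
    intersects with a subjective chain criterion.  Returns the information
    chain and the final SelectionResult; ``status == "none_informative"``
    means not even the chain peak cleared the objective bar.
    """
    scores = score_features(matrix, gamma=gamma, c=c, mode=mode)
    chain = build_chain(scores)
    result = sample_cutoff(scores, w=w, z0=z0)
    if result.status == "none_informative" or refine is None:
        return chain, result
    if refine == "fraction":
        sub = fraction_cutoff(chain, refine_param if refine_param is not None else 0.8)
    elif refine == "top_proportion":
        sub = top_proportion_cutoff(chain, refine_param if refine_param is not None else 0.01)
    elif refine == "entropy":
        sub = entropy_criterion(chain, delta=refine_param if refine_param is not None else 0.01)
    else:
        raise ValueError(f"unknown refinement: {refine!r}")
    keep = set(result.selected) & set(sub.selected)
    selected = [f for f in chain.index if f in keep]
    decisions = result.decisions & sub.decisions.reindex(result.decisions.index)
    combined = SelectionResult(
        f"sample_cutoff+{refine}",
        {**result.parameters, **{f"refine_{k}": v for k, v in sub.parameters.items()}},
        result.threshold,
        selected,
        decisions,
        "ok" if selected else "none_informative",
    )
    return chain, combined
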