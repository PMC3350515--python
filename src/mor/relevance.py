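"""The Measure of Relevance (MoR) and the information chain.

For each feature j the MoR combines three ingredients computed on the
U-transformed (pooled-rank) data:

* ``B`` — the *biological difference*: the difference of the two group means
  (an unbiased estimate of the population mean difference on the U scale);
* ``S`` — the dispersion: the pooled standard deviation for independent
  groups, or the standard deviation of the within-pair differences for
  matched samples;
* ``O`` — the *overlap factor*: a two-proportion z-like statistic comparing
  how the two groups split around a pooled quantile (independent design), or
  the sign balance of the nonzero pair differences (dependent design).

The combined score is ``MoR = c * O * B / S`` with a common weighting factor
``c`` (default 1).  O and B both measure group-1 dominance and flip together
when the group order is reversed, so the score is evaluated as
``c * |O| * B / S``: the magnitude is the full three-factor product while
the sign — the direction of the group difference — is carried once, by B.
Large |MoR| marks biomarker candidates; swapping the group labels negates
the score exactly.  Sorting features by decreasing |MoR|
yields the *information chain* that the selection criteria operate on.

For very small samples with many continuous features, rank ties make many
features share identical ``B`` values; ``mode="raw"`` computes B and S on the
original scale instead (O stays rank-based — it is invariant under strictly
monotone transforms either way).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .data import FeatureMatrix, transform

__all__ = [
    "RelevanceScore",
    "biological_difference",
    "dispersion",
    "overlap_independent",
    "overlap_dependent",
    "score_features",
    "build_chain",
    "write_scores",
    "read_scores",
]

#: stands in for an infinite raw-mode score (S = 0 with B != 0); flagged, never silent
RAW_DEGENERATE_SENTINEL = 1e6


@dataclass(frozen=True)
class RelevanceScore:
    """Per-feature MoR decomposition."""

    feature: str
    B: float
    S: float
    O: float
    mor: float
    n1: int
    n2: int
    degenerate: bool
    mode: str


def biological_difference(u1: np.ndarray, u2: np.ndarray) -> np.ndarray | float:
    """Difference of group means, group 1 minus group 2 (missing-aware).

    On the U scale this lies in [-0.5, 0.5]; |B| = 0.5 exactly at complete
    separation of the two groups.
    """
    u1, u2 = np.asarray(u1, float), np.asarray(u2, float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        return np.nanmean(u1, axis=0) - np.nanmean(u2, axis=0)


def dispersion(
    u1: np.ndarray,
    u2: np.ndarray,
    design: Literal["independent", "dependent"] = "independent",
) -> np.ndarray | float:
    """Dispersion factor S.

    Independent: pooled standard deviation
    sqrt(((n1-1)s1^2 + (n2-1)s2^2)/(n1+n2-2)) with s_m^2 the per-group
    maximum-likelihood variances (S is deliberately not an unbiased
    estimator of the pooled sd; it is a descriptive dispersion scale).
    Dependent: the standard deviation of the within-pair differences,
    sqrt(s1^2 + s2^2 - 2*s12), with ``u1``/``u2`` pair-aligned row-wise
    (pairs with a missing member are dropped).
    """
    u1, u2 = np.asarray(u1, float), np.asarray(u2, float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if design == "dependent":
            d = u1 - u2  # NaN if either member missing
            return _nanstd(d)
        n1 = np.sum(~np.isnan(u1), axis=0)
        n2 = np.sum(~np.isnan(u2), axis=0)
        s1 = np.nanvar(u1, axis=0, ddof=0)
        s2 = np.nanvar(u2, axis=0, ddof=0)
        denom = n1 + n2 - 2
        with np.errstate(invalid="ignore", divide="ignore"):
            pooled = ((n1 - 1) * s1 + (n2 - 1) * s2) / np.where(denom > 0, denom, np.nan)
        return np.sqrt(pooled)


def _nanstd(d: np.ndarray) -> np.ndarray | float:
    # ML convention, matching the independent-case pooled S
    n = np.sum(~np.isnan(d), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n >= 2, np.nanstd(d, axis=0, ddof=0), np.nan) if d.ndim > 1 else (
            np.nanstd(d, axis=0, ddof=0) if n >= 2 else np.nan
        )


def overlap_independent(
    u1: np.ndarray, u2: np.ndarray, gamma: float = 0.5
) -> np.ndarray | float:
    """Two-proportion overlap factor for independent groups.

    ``p_m`` is the fraction of group m's U values strictly greater than the
    gamma-quantile of the pooled U sample (gamma = 0.5: the pooled median).
    With the pooled proportion p̄ = (n1 p1 + n2 p2)/N,

        O = (p1 - p2) / sqrt(p̄ (1 - p̄) (1/n1 + 1/n2)),

    the classical z statistic for comparing two binomial proportions.  For
    untied data p̄ equals 1 - gamma up to the 1/N rank-grid resolution, so O
    behaves like a standard normal under exchangeability.  p̄ in {0, 1}
    (no information) gives O = 0.
    """
    u1, u2 = np.asarray(u1, float), np.asarray(u2, float)
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie in (0, 1)")
    pooled = np.concatenate([u1, u2], axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        q = np.nanquantile(pooled, gamma, axis=0)
        n1 = np.sum(~np.isnan(u1), axis=0)
        n2 = np.sum(~np.isnan(u2), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p1 = np.nansum(u1 > q, axis=0) / n1
            p2 = np.nansum(u2 > q, axis=0) / n2
            pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
            se = np.sqrt(pbar * (1.0 - pbar) * (1.0 / n1 + 1.0 / n2))
            o = (p1 - p2) / se
    informative = (pbar > 0) & (pbar < 1)
    return np.where(informative, o, 0.0) if np.ndim(o) else (float(o) if informative else 0.0)


def overlap_dependent(u1: np.ndarray, u2: np.ndarray) -> np.ndarray | float:
    """Sign-based overlap factor for matched pairs.

    Among the n' pairs with u1 != u2 (ties are not considered), p1 and p2 are
    the fractions of positive and negative differences; the pooled proportion
    is 0.5 by construction, so

        O = (p1 - p2) / sqrt(0.25 * 2/n').

    All pairs tied (n' = 0) gives O = 0.
    """
    u1, u2 = np.asarray(u1, float), np.asarray(u2, float)
    d = u1 - u2
    pos = np.nansum(d > 0, axis=0)
    neg = np.nansum(d < 0, axis=0)
    n_eff = pos + neg
    with np.errstate(invalid="ignore", divide="ignore"):
        o = (pos - neg) / n_eff / np.sqrt(0.25 * 2.0 / np.where(n_eff > 0, n_eff, 1))
    return np.where(n_eff > 0, o, 0.0) if np.ndim(o) else (float(o) if n_eff > 0 else 0.0)


def score_features(
    matrix: FeatureMatrix,
    gamma: float = 0.5,
    c: float = 1.0,
    mode: Literal["rank", "raw"] = "rank",
    u_method: Literal["shifted", "plus_one"] = "shifted",
) -> pd.DataFrame:
    """MoR decomposition for every scoreable feature of ``matrix``.

    Returns a DataFrame indexed by feature name with columns
    ``B, S, O, mor, n1, n2, degenerate, mode``.  Nominal features with more
    than two categories are excluded with a warning.  Features where the
    score is undefined (a group empty, fewer than two values overall, or
    zero dispersion in rank mode) are flagged degenerate with mor = 0; in
    raw mode S = 0 with B != 0 yields a flagged sign(B) * 1e6 sentinel.
    """
    keep = [k != "nominal" for k in matrix.feature_kind]
    if not all(keep):
        dropped = [n for n, k in zip(matrix.feature_names, keep) if not k]
        warnings.warn(
            f"excluding {len(dropped)} nominal feature(s) from scoring: {dropped[:5]}"
        )
        sub = FeatureMatrix(
            values=matrix.values[:, keep],
            group=matrix.group,
            design=matrix.design,
            pair_id=matrix.pair_id,
            feature_names=[n for n, k in zip(matrix.feature_names, keep) if k],
            feature_kind=[k for k in matrix.feature_kind if k != "nominal"],
        )
        return score_features(sub, gamma=gamma, c=c, mode=mode, u_method=u_method)

    tm = transform(matrix, u_method=u_method)
    u1, u2 = tm.group_u()
    n1, n2 = matrix.counts()
    dep = matrix.design == "dependent"

    if dep:
        o = overlap_dependent(u1, u2)
    else:
        o = overlap_independent(u1, u2, gamma=gamma)

    if mode == "rank":
        b = biological_difference(u1, u2)
        s = dispersion(u1, u2, design=matrix.design)
    elif mode == "raw":
        v1, v2 = matrix.group_values()
        b = biological_difference(v1, v2)
        s = dispersion(v1, v2, design=matrix.design)
    else:
        raise ValueError(f"unknown mode: {mode!r}")

    b = np.atleast_1d(np.asarray(b, float))
    s = np.atleast_1d(np.asarray(s, float))
    o = np.atleast_1d(np.asarray(o, float))

    undefined = (n1 == 0) | (n2 == 0) | ~np.isfinite(b) | ~np.isfinite(s)
    zero_s = np.isfinite(s) & (s == 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        # |O| so the score carries the direction of B once, not twice:
        # O and B both flip with group order, and their raw product would
        # erase the sign of the difference
        mor = c * np.abs(o) * b / s
    mor = np.where(undefined | zero_s, 0.0, mor)
    degenerate = undefined | zero_s
    if mode == "raw":
        # zero raw spread but a real location difference: off-scale, not zero
        sentinel = zero_s & np.isfinite(b) & (b != 0.0)
        mor = np.where(sentinel, np.sign(b) * c * RAW_DEGENERATE_SENTINEL, mor)
    mor = np.where(np.isfinite(mor), mor, 0.0)

    return pd.DataFrame(
        {
            "B": b,
            "S": s,
            "O": o,
            "mor": mor,
            "n1": n1.astype(int),
            "n2": n2.astype(int),
            "degenerate": degenerate,
            "mode": mode,
        },
        index=pd.Index(matrix.feature_names, name="feature"),
    )


def build_chain(scores: pd.DataFrame) -> pd.DataFrame:
    """Information chain: features sorted by |mor| descending.

    Ties keep the input order (stable sort).  Adds a 1-based ``chain_rank``
    column.
    """
    order = np.argsort(-np.abs(scores["mor"].to_numpy()), kind="stable")
    chain = scores.iloc[order].copy()
    chain["chain_rank"] = np.arange(1, len(chain) + 1)
    return chain


def write_scores(scores: pd.DataFrame, path) -> None:
    """Write a score/chain table as round-trippable TSV."""
    scores.to_csv(path, sep="\t", float_format="%.6g")


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature")
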