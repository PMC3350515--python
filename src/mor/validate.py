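"""Sensitivity/specificity evaluation harness and baseline comparators.

The harness answers the three classical questions one asks of a new metric
scale — objectivity, reliability, validity — by simulating screening studies
with known ground truth and measuring, per condition:

* sensitivity: fraction of truly informative features selected;
* specificity: fraction of truly non-informative features not selected.

Baselines are the standard per-feature test batteries (two-sample /
paired t-tests, optionally Bonferroni-corrected, and their rank/sign
nonparametric counterparts) and, qualitatively, a random-forest importance
screen.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from .data import FeatureMatrix
from .relevance import build_chain, score_features
from .selection import Z0_DEFAULT, sample_cutoff
from .simulate import NBD_CLASSES, SimulationConfig, generate

__all__ = [
    "evaluate",
    "baseline_tests",
    "baseline_forest",
    "run_study",
    "mor_select",
    "plot_chain",
    "plot_mor_boxplots",
]


def evaluate(
    selected: Iterable[str] | np.ndarray,
    truth_mask: np.ndarray,
    feature_names: list[str] | None = None,
) -> tuple[float, float]:
    """(sensitivity, specificity) of a selection against a truth mask.

    ``selected`` is either a boolean per-feature vector aligned with the
    mask, or an iterable of selected names resolved via ``feature_names``.
    An empty truth class leaves the corresponding metric undefined (NaN),
    never 0.
    """
    truth_mask = np.asarray(truth_mask, dtype=bool)
    sel = np.asarray(selected)
    if sel.dtype != bool:
        if feature_names is None:
            raise ValueError("feature_names required when selected is a name list")
        chosen = set(selected)
        sel = np.array([f in chosen for f in feature_names])
    if sel.shape != truth_mask.shape:
        raise ValueError("selection and truth mask have different lengths")
    n_pos = truth_mask.sum()
    n_neg = (~truth_mask).sum()
    sens = float(sel[truth_mask].mean()) if n_pos else float("nan")
    spec = float((~sel[~truth_mask]).mean()) if n_neg else float("nan")
    return sens, spec


def baseline_tests(
    matrix: FeatureMatrix,
    method: Literal["t_test", "t_test_bonferroni", "rank_test", "sign_test"] = "t_test",
    alpha: float = 0.05,
) -> np.ndarray:
    """Per-feature two-sided hypothesis-test battery; returns the rejected set.

    Independent design: two-sample t-test or Wilcoxon rank-sum; dependent:
    paired t-test, Wilcoxon signed-rank, or sign test.  ``t_test_bonferroni``
    tests at level alpha / p (family = all scored features).
    """
    v1, v2 = matrix.group_values()
    p = matrix.n_features
    level = alpha / p if method == "t_test_bonferroni" else alpha
    dep = matrix.design == "dependent"
    if method in ("t_test", "t_test_bonferroni"):
        if dep:
            res = stats.ttest_rel(v1, v2, axis=0, nan_policy="omit")
        else:
            res = stats.ttest_ind(v1, v2, axis=0, nan_policy="omit")
        pvals = np.asarray(res.pvalue)
    elif method == "rank_test":
        if dep:
            d = v1 - v2
            pvals = np.array([_signed_rank_p(d[:, j]) for j in range(p)])
        else:
            res = stats.mannwhitneyu(v1, v2, axis=0, nan_policy="omit")
            pvals = np.asarray(res.pvalue)
    elif method == "sign_test":
        if not dep:
            raise ValueError("sign_test applies to the dependent design only")
        d = v1 - v2
        pvals = np.array([_sign_test_p(d[:, j]) for j in range(p)])
    else:
        raise ValueError(f"unknown method: {method!r}")
    return np.nan_to_num(pvals, nan=1.0) <= level


def _signed_rank_p(d: np.ndarray) -> float:
    d = d[~np.isnan(d)]
    d = d[d != 0]
    if len(d) < 2:
        return 1.0
    return float(stats.wilcoxon(d).pvalue)


def _sign_test_p(d: np.ndarray) -> float:
    d = d[~np.isnan(d)]
    pos, neg = int((d > 0).sum()), int((d < 0).sum())
    n = pos + neg
    if n == 0:
        return 1.0
    return float(stats.binomtest(pos, n, 0.5).pvalue)


def baseline_forest(
    matrix: FeatureMatrix,
    n_trees: int = 500,
    seed: int | None = None,
    quantile: float = 0.25,
    n_repeats: int = 10,
) -> np.ndarray:
    """Random-forest importance screen (qualitative baseline only).

    Fits a randomized-tree ensemble to predict the group label and selects
    features whose permutation importance stays positive at the given
    quantile across shuffles — noise features hover at zero importance.
    Intended for illustration on modest feature counts; the tree baseline's
    selection rule has no canonical definition, so it is never part of the
    numeric study comparisons.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.inspection import permutation_importance

    x = np.nan_to_num(matrix.values, nan=0.0)
    y = (matrix.group == matrix.group_levels[0]).astype(int)
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf.fit(x, y)
    imp = permutation_importance(
        rf, x, y, n_repeats=n_repeats, random_state=seed
    ).importances
    return np.quantile(imp, quantile, axis=1) > 0


def mor_select(
    matrix: FeatureMatrix,
    w: float = 1.0,
    z0: float = Z0_DEFAULT,
    gamma: float = 0.5,
    c: float = 1.0,
    mode: str = "rank",
) -> np.ndarray:
    """Boolean per-feature selection by MoR + sample-related cut-off."""
    scores = score_features(matrix, gamma=gamma, c=c, mode=mode)
    return sample_cutoff(scores, w=w, z0=z0).decisions.to_numpy()


_METHODS = {
    "mor": lambda m: mor_select(m),
    "t_test": lambda m: baseline_tests(m, "t_test"),
    "t_test_bonferroni": lambda m: baseline_tests(m, "t_test_bonferroni"),
    "rank_test": lambda m: baseline_tests(m, "rank_test"),
}

# (label, design, n1, n2) grids mirroring the study tables
_INDEP_SIZES = [(12, 10), (15, 15), (30, 30)]
_DEP_SIZES = [11, 15, 30]


def _study_conditions(study: str) -> list[dict]:
    conds: list[dict] = []
    if study == "objectivity":
        for cls in ("high", "semi", "none"):
            for n1, n2 in _INDEP_SIZES:
                conds.append(dict(distribution="normal", design="independent",
                                  n1=n1, n2=n2, info_class=cls, methods=["mor", "rank_test"]))
            for n in _DEP_SIZES:
                conds.append(dict(distribution="normal", design="dependent",
                                  n1=n, n2=n, info_class=cls, methods=["mor", "rank_test"]))
    elif study == "reliability":
        for dist in ("uniform", "bimodal"):
            for cls in ("high", "semi"):
                for n1, n2 in [(12, 10), (14, 16), (30, 30)]:
                    conds.append(dict(distribution=dist, design="independent",
                                      n1=n1, n2=n2, info_class=cls, methods=["mor", "rank_test"]))
    elif study == "validity":
        methods = ["mor", "t_test", "t_test_bonferroni"]
        for cls in ("high", "semi", "none"):
            for n1, n2 in [(12, 10), (14, 16), (30, 30)]:
                conds.append(dict(distribution="normal", design="independent",
                                  n1=n1, n2=n2, info_class=cls, methods=methods))
            for n in _DEP_SIZES:
                conds.append(dict(distribution="normal", design="dependent",
                                  n1=n, n2=n, info_class=cls, methods=methods))
    elif study == "boxplot":
        for design in ("independent", "dependent"):
            for dtype in ("metric", "binary"):
                for cls in ("high", "semi", "none"):
                    conds.append(dict(distribution="normal", design=design,
                                      n1=30, n2=30, info_class=cls,
                                      dtype=dtype, methods=[]))
    else:
        raise ValueError(f"unknown study: {study!r}")
    return conds


def run_study(
    study: Literal["objectivity", "reliability", "validity", "boxplot"],
    runs: int = 100,
    seed: int | None = 0,
    p: int = 1000,
    n_informative: int = 10,
    conditions: list[dict] | None = None,
) -> pd.DataFrame:
    """Run a simulation study grid: generate → score → select → evaluate.

    Returns a tidy MetricsTable with one row per (condition, method):
    sensitivity and specificity averaged over ``runs`` replicate datasets.
    The ``boxplot`` study instead returns the raw MoR values per condition
    (long format), for comparing the score's distribution across data types
    and designs at matched information content.

    ``conditions`` overrides the built-in grid (same dict schema) — handy
    for desk-scale spot checks.
    """
    from .simulate import dichotomize_at_median

    rng = np.random.default_rng(seed)
    conds = conditions if conditions is not None else _study_conditions(study)
    rows = []
    for cond in conds:
        cfg = SimulationConfig(
            p=p,
            n_informative=n_informative,
            nbd=NBD_CLASSES[cond.get("info_class", "high")],
            distribution=cond.get("distribution", "normal"),
            design=cond.get("design", "independent"),
            n1=cond["n1"],
            n2=cond["n2"],
        )
        if study == "boxplot":
            # pool raw MoR values across runs instead of selection metrics
            cfg = SimulationConfig(**{**cfg.__dict__, "n_informative": p})
            for r in range(runs):
                matrix, _ = generate(cfg, rng=rng)
                if cond.get("dtype") == "binary":
                    matrix = dichotomize_at_median(matrix)
                mors = score_features(matrix)["mor"].to_numpy()
                rows.append(pd.DataFrame({
                    "design": cfg.design, "dtype": cond.get("dtype", "metric"),
                    "info_class": cond.get("info_class"), "run": r, "mor": mors,
                }))
            continue
        acc: dict[str, list[tuple[float, float]]] = {m: [] for m in cond["methods"]}
        for _ in range(runs):
            matrix, mask = generate(cfg, rng=rng)
            for m in cond["methods"]:
                sel = _METHODS[m](matrix)
                acc[m].append(evaluate(sel, mask))
        for m, vals in acc.items():
            arr = np.array(vals, dtype=float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # empty truth class
                mean_sens = float(np.nanmean(arr[:, 0]))
                mean_spec = float(np.nanmean(arr[:, 1]))
            rows.append({
                "study": study,
                "distribution": cfg.distribution,
                "design": cfg.design,
                "n1": cfg.n1,
                "n2": cfg.n2,
                "info_class": cond.get("info_class"),
                "nbd": cfg.nbd,
                "method": m,
                "sensitivity": mean_sens,
                "specificity": mean_spec,
                "runs": runs,
            })
    if study == "boxplot":
        return pd.concat(rows, ignore_index=True)
    return pd.DataFrame(rows)


def plot_chain(chain: pd.DataFrame, threshold: float | None = None,
               top: int = 50, path=None):
    """Course of the best |MoR| values along the information chain.

    Optionally draws the selection threshold as a horizontal line.  Saves
    to ``path`` when given, else returns the matplotlib Axes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    vals = np.abs(chain["mor"].to_numpy())[:top]
    ax.plot(np.arange(1, len(vals) + 1), vals, marker="o", ms=3, lw=1)
    if threshold is not None:
        ax.axhline(threshold, color="red", lw=1, label=f"cut-off {threshold:.3g}")
        ax.legend(frameon=False)
    ax.set_xlabel("chain position")
    ax.set_ylabel("|MoR|")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return ax


def plot_mor_boxplots(box_table: pd.DataFrame, path=None):
    """Boxplots of MoR values per (design, data type, information class).

    ``box_table`` is the long-format output of ``run_study("boxplot", ...)``;
    matched information content should give similar boxes across designs and
    data types.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    groups = list(box_table.groupby(["design", "dtype", "info_class"]))
    fig, ax = plt.subplots(figsize=(1.2 * len(groups) + 2, 4))
    ax.boxplot([np.abs(sub["mor"].to_numpy()) for _, sub in groups],
               tick_labels=["\n".join(map(str, key)) for key, _ in groups],
               showfliers=False)
    ax.set_ylabel("|MoR|")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return ax
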