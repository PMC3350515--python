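"""Two-sample feature matrices and the rank/U-transformation.

A :class:`FeatureMatrix` holds a samples-by-features table together with a
two-level group label per sample.  Downstream scoring never looks at the raw
measurement scale: every feature is first converted to midranks over the
*pooled* sample (both groups jointly) and the ranks are mapped into the open
unit interval.  After this U-transformation features of different scales and
types (metric, ordinal, binary) live on one common scale and can be compared
directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

Design = Literal["independent", "dependent"]
FeatureKind = Literal["metric", "ordinal", "binary", "nominal"]

__all__ = [
    "FeatureMatrix",
    "TransformedMatrix",
    "rank_transform",
    "u_transform",
    "transform",
    "read_table",
    "infer_feature_kinds",
]


def rank_transform(x: np.ndarray) -> np.ndarray:
    """Midranks of ``x`` over the whole pooled sample, missing-aware.

    Ranks are computed jointly over both groups; ties receive midranks and
    missing values stay missing (they do not consume a rank).  Accepts a
    vector or a samples-by-features matrix (ranked column-wise).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return rankdata(x, method="average", nan_policy="omit")
    return rankdata(x, method="average", nan_policy="omit", axis=0)


def u_transform(
    ranks: np.ndarray,
    n: int | np.ndarray | None = None,
    method: Literal["shifted", "plus_one"] = "shifted",
) -> np.ndarray:
    """Map midranks on 1..N into the open unit interval.

    The default ``shifted`` rule is U = (R - 0.5)/N, which places an untied
    full rank set symmetrically around 0.5: the pooled mean is exactly 0.5
    and the pooled median equals 0.5 for even N.  ``plus_one`` uses the
    classical alternative R/(N+1), which shares the qualitative properties.

    ``n`` is the count of non-missing values (per column for matrices);
    inferred from the non-NaN entries when omitted.
    """
    ranks = np.asarray(ranks, dtype=float)
    if n is None:
        axis = 0 if ranks.ndim > 1 else None
        n = np.sum(~np.isnan(ranks), axis=axis)
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        if method == "shifted":
            u = (ranks - 0.5) / n
        elif method == "plus_one":
            u = ranks / (n + 1.0)
        else:
            raise ValueError(f"unknown u_transform method: {method!r}")
    return u


def infer_feature_kinds(values: pd.DataFrame) -> list[str]:
    """Per-feature kind from the data alone.

    At most two distinct non-missing values coded 0/1 -> binary; two-valued
    on any other coding -> ordinal; other numeric -> metric; non-numeric ->
    nominal (scoring rejects nominal features with a warning).
    """
    kinds: list[str] = []
    for col in values.columns:
        s = values[col].dropna()
        numeric = pd.api.types.is_numeric_dtype(s)
        if numeric and s.nunique() <= 2:
            kinds.append("binary" if set(s.unique()) <= {0, 1} else "ordinal")
        elif numeric:
            kinds.append("metric")
        else:
            kinds.append("nominal")
    return kinds


@dataclass
class FeatureMatrix:
    """Samples-by-features values with a two-level group structure.

    Parameters
    ----------
    values : (n, p) float array; NaN marks missing (per-feature complete case).
    group : length-n label vector with exactly two distinct levels.
    design : "independent" for two unrelated groups, "dependent" for
        matched/paired samples (then ``pair_id`` is required and every pair
        occurs exactly once in each group).
    pair_id : per-sample pair/subject identifier (dependent design only).
    feature_names : p names; generated as f0..f{p-1} when omitted.
    feature_kind : per-feature "metric" / "ordinal" / "binary" / "nominal".
    """

    values: np.ndarray
    group: np.ndarray
    design: Design = "independent"
    pair_id: np.ndarray | None = None
    feature_names: list[str] = field(default_factory=list)
    feature_kind: list[str] = field(default_factory=list)
    levels: tuple | None = None  # (group 1 label, group 2 label); appearance order if None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.group = np.asarray(self.group)
        n, p = self.values.shape
        if self.group.shape[0] != n:
            raise ValueError(f"group has {self.group.shape[0]} labels for {n} samples")
        found = pd.unique(self.group[~pd.isna(self.group)])
        if len(found) != 2:
            raise ValueError(
                f"exactly two group levels required, found {len(found)}: {list(found)!r}"
            )
        if self.levels is not None:
            if set(self.levels) != set(found):
                raise ValueError(f"levels {self.levels!r} do not match the data {list(found)!r}")
            self._levels = (self.levels[0], self.levels[1])
        else:
            self._levels = (found[0], found[1])
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(p)]
        if len(self.feature_names) != p:
            raise ValueError("feature_names length does not match feature count")
        if not self.feature_kind:
            self.feature_kind = infer_feature_kinds(
                pd.DataFrame(self.values, columns=self.feature_names)
            )
        if self.design == "dependent":
            if self.pair_id is None:
                raise ValueError("dependent design requires pair_id")
            self.pair_id = np.asarray(self.pair_id)
            g1, g2 = self.group_masks()
            ids1, ids2 = sorted(self.pair_id[g1]), sorted(self.pair_id[g2])
            if len(ids1) != len(set(ids1)) or ids1 != ids2:
                raise ValueError(
                    "dependent design: every pair_id must occur exactly once per group"
                )
        for j, kind in enumerate(self.feature_kind):
            if kind == "binary":
                col = self.values[:, j]
                ok = np.isnan(col) | np.isin(col, (0.0, 1.0))
                if not ok.all():
                    raise ValueError(
                        f"binary feature {self.feature_names[j]!r} has values outside {{0, 1}}"
                    )

    # -- structure ---------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def group_levels(self) -> tuple:
        """The two group levels; the first is treated as group 1 (m=1)."""
        return self._levels

    def group_masks(self) -> tuple[np.ndarray, np.ndarray]:
        return self.group == self._levels[0], self.group == self._levels[1]

    def group_values(self) -> tuple[np.ndarray, np.ndarray]:
        """Raw values split by group; dependent design returns pair-aligned rows."""
        g1, g2 = self.group_masks()
        v1, v2 = self.values[g1], self.values[g2]
        if self.design == "dependent":
            o1 = np.argsort(self.pair_id[g1], kind="stable")
            o2 = np.argsort(self.pair_id[g2], kind="stable")
            return v1[o1], v2[o2]
        return v1, v2

    def counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-feature non-missing counts (n1j, n2j)."""
        v1, v2 = self.group_values()
        return (
            np.sum(~np.isnan(v1), axis=0),
            np.sum(~np.isnan(v2), axis=0),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "group", self.group)
        if self.pair_id is not None:
            df.insert(1, "pair", self.pair_id)
        return df


@dataclass
class TransformedMatrix:
    """Rank- and U-transformed view of a :class:`FeatureMatrix`."""

    rank_values: np.ndarray
    u_values: np.ndarray
    source: FeatureMatrix

    def group_u(self) -> tuple[np.ndarray, np.ndarray]:
        g1, g2 = self.source.group_masks()
        u1, u2 = self.u_values[g1], self.u_values[g2]
        if self.source.design == "dependent":
            o1 = np.argsort(self.source.pair_id[g1], kind="stable")
            o2 = np.argsort(self.source.pair_id[g2], kind="stable")
            return u1[o1], u2[o2]
        return u1, u2


def transform(
    matrix: FeatureMatrix, u_method: Literal["shifted", "plus_one"] = "shifted"
) -> TransformedMatrix:
    """Pooled-sample rank + U transformation of every feature."""
    ranks = rank_transform(matrix.values)
    u = u_transform(ranks, method=u_method)
    return TransformedMatrix(rank_values=ranks, u_values=u, source=matrix)


def _read_kind_sidecar(path: Path) -> dict[str, str]:
    kinds: dict[str, str] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" in line:
            key, _, val = line.partition("=")
        else:
            key, _, val = line.partition(":")
        kinds[key.strip()] = val.strip()
    return kinds


def read_table(
    path: str | Path,
    group_col: str,
    pair_col: str | None = None,
    sep: str | None = None,
    kinds_path: str | Path | None = None,
    feature_cols: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Read a delimited text table (samples as rows) into a FeatureMatrix.

    ``sep=None`` sniffs comma vs tab from the extension.  A sidecar key-value
    text file (``feature = kind`` per line) overrides the automatic
    feature-kind inference.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if group_col not in df.columns:
        raise ValueError(f"group column {group_col!r} not in table")
    drop = [group_col] + ([pair_col] if pair_col else [])
    feats = list(feature_cols) if feature_cols is not None else [
        c for c in df.columns if c not in drop
    ]
    values = df[feats].to_numpy(dtype=float)
    kinds = infer_feature_kinds(df[feats])
    if kinds_path is not None:
        overrides = _read_kind_sidecar(Path(kinds_path))
        unknown = set(overrides) - set(feats)
        if unknown:
            warnings.warn(f"kind sidecar names unknown features: {sorted(unknown)}")
        kinds = [overrides.get(c, k) for c, k in zip(feats, kinds)]
    return FeatureMatrix(
        values=values,
        group=df[group_col].to_numpy(),
        design="dependent" if pair_col else "independent",
        pair_id=df[pair_col].to_numpy() if pair_col else None,
        feature_names=feats,
        feature_kind=kinds,
    )
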