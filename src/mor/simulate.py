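"""Synthetic two-sample study generators.

Each generated dataset mimics a screening study: ``p`` features measured on
two groups, of which ``n_informative`` carry a genuine group difference of
configurable standardized size (the *normalized biological difference*,
NBD: mean shift in pooled-standard-deviation units) and the rest are pure
noise.  All features — informative or not — come from the same distribution
family, only the location parameters differ.

Distribution families
---------------------
normal     N(0, 1) vs N(NBD, 1).
uniform    equal-width uniforms of unit variance (width sqrt(12)), the
           second group's interval shifted by NBD.
bimodal    equal mixture of two unit-sd normals at +-a (default a = 2),
           rescaled to unit variance, second group shifted by NBD.
bernoulli  success probabilities (0.5 + NBD/4, 0.5 - NBD/4), which solve
           |p1 - p2| / sqrt(pbar (1 - pbar)) = NBD symmetrically about 0.5;
           NBD > 2 is unattainable and raises.

Dependent (matched-pairs) design adds a shared per-pair component giving
within-pair correlation ``rho`` (default 0.5); the informative shift is then
expressed in standard deviations of the *pair difference*, the effect scale
a paired analysis sees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.stats import norm

from .data import FeatureMatrix

__all__ = ["SimulationConfig", "generate", "dichotomize_at_median", "NBD_CLASSES"]

#: standardized effect sizes of the three information-content classes
NBD_CLASSES = {"high": 2.0, "semi": 1.0, "none": 0.0}


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for one synthetic screening dataset.

    ``nbd`` is the standardized effect of the informative block; the class
    shorthands in :data:`NBD_CLASSES` (high = 2, semi = 1, none = 0) mirror
    the three information-content levels of the study designs.
    """

    p: int = 1000
    n_informative: int = 10
    nbd: float = 2.0
    distribution: Literal["normal", "uniform", "bimodal", "bernoulli"] = "normal"
    design: Literal["independent", "dependent"] = "independent"
    n1: int = 15
    n2: int = 15
    pair_correlation: float = 0.5
    bimodal_separation: float = 2.0
    seed: int | None = None

    def __post_init__(self):
        if self.n_informative > self.p:
            raise ValueError("n_informative must not exceed p")
        if self.nbd < 0:
            raise ValueError("nbd must be non-negative")
        if not 0.0 <= self.pair_correlation < 1.0:
            raise ValueError("pair_correlation must lie in [0, 1)")
        if self.design == "dependent" and self.n1 != self.n2:
            raise ValueError("dependent design requires n1 == n2 (pairs)")

    def with_class(self, info_class: str) -> "SimulationConfig":
        return replace(self, nbd=NBD_CLASSES[info_class])


def _unit_variance_draw(rng, dist, size, sep):
    """Zero-mean, unit-variance noise from the requested family."""
    if dist == "normal":
        return rng.standard_normal(size)
    if dist == "uniform":
        w = np.sqrt(12.0)  # unit-variance width
        return rng.uniform(-w / 2, w / 2, size)
    if dist == "bimodal":
        comp = rng.choice((-sep, sep), size=size)
        x = comp + rng.standard_normal(size)
        return x / np.sqrt(1.0 + sep**2)
    raise ValueError(f"unknown distribution: {dist!r}")


def generate(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[FeatureMatrix, np.ndarray]:
    """One synthetic dataset plus its ground-truth informative mask.

    Returns ``(matrix, mask)`` where ``mask[j]`` is True for the
    ``n_informative`` features carrying the configured effect (always the
    first block, so chain-recovery checks are straightforward).  A fixed
    seed (via ``config.seed`` or an explicit generator) reproduces the
    matrix bit for bit.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p, k = config.p, config.n_informative
    mask = np.zeros(p, dtype=bool)
    mask[:k] = True
    dep = config.design == "dependent"
    n1, n2 = config.n1, config.n2

    if config.distribution == "bernoulli":
        if config.nbd > 2.0:
            raise ValueError(
                "bernoulli effects above NBD = 2 are unattainable (proportions leave [0, 1])"
            )
        p1 = np.full(p, 0.5)
        p2 = np.full(p, 0.5)
        p1[mask] = 0.5 + config.nbd / 4.0
        p2[mask] = 0.5 - config.nbd / 4.0
        if dep:
            # shared latent normal; dichotomized at the per-group probability
            rho = config.pair_correlation
            z = rng.standard_normal((n1, p))
            e1 = np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.standard_normal((n1, p))
            e2 = np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.standard_normal((n1, p))
            x1 = (e1 < norm.ppf(p1)).astype(float)
            x2 = (e2 < norm.ppf(p2)).astype(float)
        else:
            x1 = (rng.random((n1, p)) < p1).astype(float)
            x2 = (rng.random((n2, p)) < p2).astype(float)
        kinds = ["binary"] * p
    else:
        dist, sep = config.distribution, config.bimodal_separation
        if dep:
            rho = config.pair_correlation
            shared = _unit_variance_draw(rng, dist, (n1, p), sep)
            x1 = np.sqrt(rho) * shared + np.sqrt(1 - rho) * _unit_variance_draw(
                rng, dist, (n1, p), sep
            )
            x2 = np.sqrt(rho) * shared + np.sqrt(1 - rho) * _unit_variance_draw(
                rng, dist, (n1, p), sep
            )
            # effect in sd units of the pair difference
            shift = config.nbd * np.sqrt(2.0 * (1.0 - rho))
        else:
            x1 = _unit_variance_draw(rng, dist, (n1, p), sep)
            x2 = _unit_variance_draw(rng, dist, (n2, p), sep)
            shift = config.nbd
        x2[:, mask] += shift
        kinds = ["metric"] * p

    values = np.vstack([x1, x2])
    group = np.array(["g1"] * n1 + ["g2"] * x2.shape[0])
    matrix = FeatureMatrix(
        values=values,
        group=group,
        design=config.design,
        pair_id=np.concatenate([np.arange(n1)] * 2) if dep else None,
        feature_names=[f"f{j}" for j in range(p)],
        feature_kind=kinds,
    )
    return matrix, mask


def dichotomize_at_median(matrix: FeatureMatrix) -> FeatureMatrix:
    """Binarize every feature at its whole-pooled-sample median.

    Values strictly greater than the pooled median become 1, all others 0
    (a constant feature therefore maps to all zeros).  Missing values stay
    missing.  Group structure and design are preserved, so metric and
    binary versions of the same study carry comparable information.
    """
    med = np.nanmedian(matrix.values, axis=0)
    binary = (matrix.values > med).astype(float)
    binary[np.isnan(matrix.values)] = np.nan
    return FeatureMatrix(
        values=binary,
        group=matrix.group,
        design=matrix.design,
        pair_id=matrix.pair_id,
        feature_names=list(matrix.feature_names),
        feature_kind=["binary"] * matrix.n_features,
    )
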