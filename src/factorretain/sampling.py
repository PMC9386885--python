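"""Multivariate-normal sampling from a population correlation matrix.

Data are drawn by the classical spectral route: with ``R = U diag(d) U'``,
set ``F = U diag(d)**0.5`` and return ``Z = X F'`` where ``X`` is an N x J
matrix of independent standard normals.  ``Z`` then has population
correlation matrix ``R`` with standard-normal margins, which makes
thresholding at a fixed cut point a clean probit dichotomization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "SampleMatrix",
    "BinaryMatrix",
    "mvn_factor",
    "draw_from_corr",
    "draw_continuous_sample",
    "dichotomize",
    "DELTA_50_50",
    "DELTA_75_25",
]

#: thresholds for the two dichotomization regimes: an even split, and a
#: skewed split with 75% zeros / 25% ones.
DELTA_50_50 = 0.0
DELTA_75_25 = float(norm.ppf(0.75))


@dataclass
class SampleMatrix:
    """An N x J continuous draw plus provenance labels."""

    values: np.ndarray
    source_condition: dict = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]


@dataclass
class BinaryMatrix:
    """A 0/1 matrix obtained by thresholding a continuous sample."""

    values: np.ndarray
    delta: float
    source_condition: dict = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]


def mvn_factor(R: np.ndarray) -> np.ndarray:
    """Spectral square root F = U d**0.5 of a correlation matrix.

    Eigenvalues are clipped at zero before the square root so that tiny
    negative round-off (-1e-15) does not poison the factor; F @ F.T
    reproduces R up to that clipping.
    """
    R = np.asarray(R, dtype=float)
    if not np.all(np.isfinite(R)):
        raise ValueError("correlation matrix contains non-finite entries")
    d, U = np.linalg.eigh(R)
    d = np.clip(d, 0.0, None)
    return U * np.sqrt(d)


def draw_from_corr(R: np.ndarray, n_obs: int, rng: np.random.Generator) -> np.ndarray:
    """Draw an n_obs x J multivariate-normal matrix with correlation R."""
    F = mvn_factor(R)
    X = rng.standard_normal((n_obs, R.shape[0]))
    return X @ F.T


def draw_continuous_sample(model, n_obs: int, rng: np.random.Generator,
                           labels: dict | None = None) -> SampleMatrix:
    """Draw one continuous sample from a population model."""
    Z = draw_from_corr(model.R, n_obs, rng)
    return SampleMatrix(values=Z, source_condition=dict(labels or {}))


def dichotomize(sample: SampleMatrix, delta: float) -> BinaryMatrix:
    """Threshold a continuous sample: 1 where value > delta, else 0.

    Ties at exactly ``delta`` map to 0 — a probability-zero event for
    continuous data, fixed for determinism.
    """
    if not np.isfinite(delta):
        raise ValueError("delta must be finite")
    vals = (sample.values > delta).astype(np.int8)
    return BinaryMatrix(values=vals, delta=float(delta),
                        source_condition=dict(sample.source_condition))
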