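"""Pearson and tetrachoric correlation estimation with PSD repair.

The tetrachoric coefficient treats each binary item as a thresholded
standard-normal variable.  With the thresholds fixed at the normal
quantiles of the observed margins, the profile likelihood of the 2x2
table depends on rho only through the (1,1) quadrant probability, and the
maximum-likelihood estimate is the rho whose bivariate-normal quadrant
probability matches the observed cell proportion.  That probability is
strictly increasing in rho, so the estimate is found by bracketing root
search — equivalent to, but far more stable than, a direct search on the
likelihood surface.

Pairwise-assembled tetrachoric matrices are not guaranteed positive
semidefinite; ``repair_psd`` clips the spectrum and rescales back to unit
diagonal, flagging the estimate so downstream consumers know.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import multivariate_normal, norm

__all__ = [
    "CorrelationEstimate",
    "pearson_matrix",
    "tetrachoric_pair",
    "tetrachoric_matrix",
    "repair_psd",
    "DegenerateColumnError",
]

logger = logging.getLogger(__name__)

_RHO_BOUND = 0.999
_CLIP_EIG = 1e-6


class DegenerateColumnError(ValueError):
    """A column with zero variance (or an all-0/all-1 margin)."""


@dataclass
class CorrelationEstimate:
    """A J x J symmetric unit-diagonal correlation estimate."""

    R_hat: np.ndarray
    kind: str  # "pearson" | "tetrachoric"
    n_obs: int
    repaired: bool = False

    @property
    def n_items(self) -> int:
        return self.R_hat.shape[0]


def pearson_matrix(X: np.ndarray, kind: str = "pearson") -> CorrelationEstimate:
    """Product-moment correlation matrix of the columns of X."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0)
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        raise DegenerateColumnError(f"constant column(s): {bad.tolist()}")
    R = np.corrcoef(X, rowvar=False)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return CorrelationEstimate(R_hat=R, kind=kind, n_obs=X.shape[0])


def _bvn_cdf(a: float, b: float, rho: float) -> float:
    return float(multivariate_normal.cdf(
        [a, b], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]],
    ))


def tetrachoric_pair(n00: float, n01: float, n10: float, n11: float) -> float:
    """Tetrachoric correlation of one 2x2 table.

    ``nxy`` counts observations with (first item = x, second item = y).
    A zero anywhere in the table triggers a +0.5 continuity correction on
    all four cells, which keeps the estimate finite in small samples.
    """
    cells = np.array([n00, n01, n10, n11], dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell counts must be non-negative")
    n = cells.sum()
    if n < 4:
        raise ValueError("need a total count of at least 4")
    if (cells[0] + cells[1] in (0.0, n)) or (cells[0] + cells[2] in (0.0, n)):
        raise DegenerateColumnError("a margin is entirely 0 or entirely 1")
    if np.any(cells == 0.0):
        cells = cells + 0.5
        n = cells.sum()
    n00, n01, n10, n11 = cells
    p0_first = (n00 + n01) / n   # P(first item = 0)
    p0_second = (n00 + n10) / n
    a = norm.ppf(p0_first)
    b = norm.ppf(p0_second)
    target = n11 / n

    def score(rho: float) -> float:
        # P(X > a, Y > b; rho) - observed p11; increasing in rho
        return 1.0 - norm.cdf(a) - norm.cdf(b) + _bvn_cdf(a, b, rho) - target

    lo, hi = -_RHO_BOUND, _RHO_BOUND
    if score(lo) >= 0.0:
        return lo
    if score(hi) <= 0.0:
        return hi
    return float(brentq(score, lo, hi, xtol=1e-10))


def tetrachoric_matrix(B) -> CorrelationEstimate:
    """Pairwise tetrachoric correlation matrix of a binary data matrix.

    Accepts a ``BinaryMatrix`` or a plain 0/1 array.  Pairwise 2x2 counts
    are assembled with matrix products; the resulting matrix is PSD-repaired
    (and flagged) if indefinite.
    """
    V = np.asarray(getattr(B, "values", B), dtype=float)
    n, J = V.shape
    ones = V.sum(axis=0)
    if np.any(ones == 0) or np.any(ones == n):
        bad = np.flatnonzero((ones == 0) | (ones == n))
        raise DegenerateColumnError(f"all-0 or all-1 column(s): {bad.tolist()}")
    N11 = V.T @ V
    N10 = V.T @ (1.0 - V)
    N01 = N10.T
    N00 = n - N11 - N10 - N01
    R = np.eye(J)
    for v in range(J):
        for w in range(v + 1, J):
            R[v, w] = R[w, v] = tetrachoric_pair(
                N00[v, w], N01[v, w], N10[v, w], N11[v, w]
            )
    est = CorrelationEstimate(R_hat=R, kind="tetrachoric", n_obs=n)
    eigmin = float(np.linalg.eigvalsh(R)[0])
    if eigmin < _CLIP_EIG:
        est = repair_psd(R, kind="tetrachoric", n_obs=n)
    return est


def repair_psd(R: np.ndarray, kind: str = "pearson", n_obs: int = 0
               ) -> CorrelationEstimate:
    """Clip the spectrum at 1e-6 and rescale back to unit diagonal.

    Positive-definite inputs pass through unchanged (repaired=False); the
    maximum entry change of an actual repair is logged.
    """
    R = np.asarray(R, dtype=float)
    if np.linalg.eigvalsh(R)[0] >= _CLIP_EIG:
        return CorrelationEstimate(R_hat=R, kind=kind, n_obs=n_obs,
                                   repaired=False)
    # the unit-diagonal rescaling can push the smallest eigenvalue back
    # below the floor, so clip at an escalating floor until it sticks
    fixed, floor = R, _CLIP_EIG
    for _ in range(60):
        d, U = np.linalg.eigh(fixed)
        if d[0] >= _CLIP_EIG:
            break
        d = np.clip(d, floor, None)
        fixed = (U * d) @ U.T
        scale = 1.0 / np.sqrt(np.diag(fixed))
        fixed = fixed * scale[:, None] * scale[None, :]
        fixed = (fixed + fixed.T) / 2.0
        np.fill_diagonal(fixed, 1.0)
        floor *= 2.0
    logger.info("PSD repair applied; max entry change %.3e",
                float(np.max(np.abs(fixed - R))))
    return CorrelationEstimate(R_hat=fixed, kind=kind, n_obs=n_obs,
                               repaired=True)
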