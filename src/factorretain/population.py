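"""Population correlation matrices for factor-retention studies.

A population is built from three layers of common variance:

* ``M1`` *major* factors with perfect simple structure — every item loads
  on exactly one major factor, with squared loading (communality) drawn
  from a small set of levels;
* ``M2`` *minor* factors that mimic the lack of fit of the factor model in
  real data: random normal loadings whose columns decay geometrically and
  whose rows are rescaled to a fixed share of the residual variance;
* item-specific unique variance absorbing the remainder.

The implied item correlation matrix is

    R = L_major @ Phi @ L_major.T + L_minor @ L_minor.T + diag(psi)

with ``Phi`` the interfactor correlation matrix of the major factors.
Minor factors are mutually uncorrelated and uncorrelated with the major
factors, so they enter without a middle matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "PopulationSpec",
    "PopulationModel",
    "build_major_loadings",
    "build_minor_loadings",
    "assemble_population",
]

_ATOL = 1e-10


class InvalidSpecError(ValueError):
    """Raised when a population specification is internally inconsistent."""


class GenerationError(RuntimeError):
    """Raised when a generated population matrix is unusable (e.g. not PD)."""


@dataclass(frozen=True)
class PopulationSpec:
    """Recipe for one population condition.

    Parameters
    ----------
    n_items : int
        Number of manifest variables J.
    n_major : int
        Number of major factors M1 (perfect simple structure).
    n_minor : int
        Number of minor factors M2; 0 disables model error entirely.
    communality_levels : tuple of float
        Discrete levels from which each item's major communality h² is
        drawn uniformly (e.g. ``(0.2, 0.3, 0.4)``).
    interfactor_corr : float
        Common correlation among all pairs of major factors, in [0, 1).
    common_ratio : float
        Multiplier of the geometric decay across minor-factor columns,
        in (0, 1].
    minor_share_rule : str
        How the minor communality derives from the major one.
        ``"half_residual"`` (default): the minor factors take half of the
        variance the major factors leave unexplained, ``h2_minor =
        0.5 * (1 - h2_major)`` (the minor-loading row norm is then the
        square root of half the residual variance).  This is the only
        share rule that keeps unique variance positive at every stated
        communality level *and* reproduces the published eigenvalue
        inflation of such populations at both low and high communalities.
        ``"half_sqrt_norm"``: row norm ``0.5 * sqrt(1 - h2_major)``, i.e.
        ``h2_minor = 0.25 * (1 - h2_major)`` — markedly weaker model error.
        ``"literal_half_sqrt"``: ``h2_minor = 0.5 * sqrt(1 - h2_major)``,
        which produces negative uniqueness for h2_major > 0.75 and is kept
        only to document why it is rejected.
    seed : int
        Seed of the population random stream; one population per condition
        is drawn from it and reused across replications.
    """

    n_items: int = 20
    n_major: int = 3
    n_minor: int = 200
    communality_levels: tuple = (0.2, 0.3, 0.4)
    interfactor_corr: float = 0.0
    common_ratio: float = 0.8
    minor_share_rule: str = "half_residual"
    seed: int = 0

    def __post_init__(self):
        if self.n_items < 1 or self.n_major < 1 or self.n_minor < 0:
            raise InvalidSpecError("counts must be positive (n_minor may be 0)")
        if self.n_items < self.n_major:
            raise InvalidSpecError(
                f"n_items ({self.n_items}) must be >= n_major ({self.n_major})"
            )
        if not all(0.0 < h < 1.0 for h in self.communality_levels):
            raise InvalidSpecError("communality levels must lie strictly in (0, 1)")
        if not (0.0 <= self.interfactor_corr < 1.0):
            raise InvalidSpecError("interfactor_corr must lie in [0, 1)")
        if not (0.0 < self.common_ratio <= 1.0):
            raise InvalidSpecError("common_ratio must lie in (0, 1]")
        if self.minor_share_rule not in ("half_residual", "half_sqrt_norm",
                                         "literal_half_sqrt"):
            raise InvalidSpecError(
                f"unknown minor_share_rule {self.minor_share_rule!r}"
            )


@dataclass
class PopulationModel:
    """A realized population: loadings, unique variances and implied R."""

    spec: PopulationSpec
    Lambda_major: np.ndarray
    Lambda_minor: np.ndarray
    Phi: np.ndarray
    psi: np.ndarray
    R: np.ndarray
    h2_major: np.ndarray
    h2_minor: np.ndarray

    @property
    def n_items(self) -> int:
        return self.R.shape[0]

    def to_json(self) -> str:
        payload = {
            "spec": asdict(self.spec),
            "Lambda_major": self.Lambda_major.tolist(),
            "Lambda_minor": self.Lambda_minor.tolist(),
            "Phi": self.Phi.tolist(),
            "psi": self.psi.tolist(),
            "R": self.R.tolist(),
            "h2_major": self.h2_major.tolist(),
            "h2_minor": self.h2_minor.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "PopulationModel":
        d = json.loads(text)
        d["spec"]["communality_levels"] = tuple(d["spec"]["communality_levels"])
        spec = PopulationSpec(**d["spec"])
        arrays = {k: np.asarray(v, dtype=float) for k, v in d.items() if k != "spec"}
        return cls(spec=spec, **arrays)


def build_major_loadings(spec: PopulationSpec, rng: np.random.Generator):
    """Major-factor loading matrix with perfect simple structure.

    Items are partitioned into ``n_major`` contiguous blocks as equal as
    possible (the first ``J mod M1`` blocks get the extra item; 20 items on
    3 factors split 7/7/6).  The item assigned to factor m receives loading
    ``sqrt(h2)`` with h² drawn uniformly from ``communality_levels``.

    Returns
    -------
    (Lambda_major, h2_major) : (J x M1 ndarray, length-J ndarray)
    """
    J, M1 = spec.n_items, spec.n_major
    base, extra = divmod(J, M1)
    sizes = [base + (1 if m < extra else 0) for m in range(M1)]
    levels = np.asarray(spec.communality_levels, dtype=float)
    h2 = levels[rng.integers(0, len(levels), size=J)]
    Lam = np.zeros((J, M1))
    j = 0
    for m, size in enumerate(sizes):
        Lam[j : j + size, m] = np.sqrt(h2[j : j + size])
        j += size
    return Lam, h2


def _minor_share(h2_major: np.ndarray, rule: str) -> np.ndarray:
    if rule == "half_residual":
        return 0.5 * (1.0 - h2_major)
    if rule == "half_sqrt_norm":
        return 0.25 * (1.0 - h2_major)
    # literal reading: half of the square root of the unexplained variance
    return 0.5 * np.sqrt(1.0 - h2_major)


def build_minor_loadings(spec: PopulationSpec, h2_major: np.ndarray,
                         rng: np.random.Generator):
    """Minor-factor loadings: geometric column decay, fixed row share.

    Entries start as independent standard normals; column m is multiplied
    by ``common_ratio**(m-1)``; each row is then rescaled so its squared
    norm equals the minor communality given by the spec's share rule.

    Returns
    -------
    (Lambda_minor, h2_minor) : (J x M2 ndarray, length-J ndarray)
    """
    h2_major = np.asarray(h2_major, dtype=float)
    J = spec.n_items
    if np.any(h2_major <= 0.0) or np.any(h2_major >= 1.0):
        raise InvalidSpecError("major communalities must lie strictly in (0, 1)")
    if spec.n_minor == 0:
        return np.zeros((J, 0)), np.zeros(J)
    h2_minor = _minor_share(h2_major, spec.minor_share_rule)
    if np.any(h2_major + h2_minor >= 1.0):
        raise InvalidSpecError(
            "minor-communality rule leaves no unique variance "
            f"(rule={spec.minor_share_rule!r}, max total communality "
            f"{np.max(h2_major + h2_minor):.3f})"
        )
    W = rng.standard_normal((J, spec.n_minor))
    W *= spec.common_ratio ** np.arange(spec.n_minor)
    norms = np.linalg.norm(W, axis=1)
    W *= (np.sqrt(h2_minor) / norms)[:, None]
    return W, h2_minor


def assemble_population(spec: PopulationSpec) -> PopulationModel:
    """Build the full population model for one condition.

    One model per condition: the random stream is created from
    ``spec.seed`` here, so every call with the same spec yields the same
    population, which is then reused across sampling replications.
    """
    rng = np.random.default_rng(spec.seed)
    Lam, h2_major = build_major_loadings(spec, rng)
    W, h2_minor = build_minor_loadings(spec, h2_major, rng)
    psi = 1.0 - h2_major - h2_minor
    if np.any(psi <= 0.0):
        raise GenerationError("nonpositive unique variance")
    M1 = spec.n_major
    Phi = np.full((M1, M1), spec.interfactor_corr)
    np.fill_diagonal(Phi, 1.0)
    R = Lam @ Phi @ Lam.T + W @ W.T + np.diag(psi)
    R = (R + R.T) / 2.0
    if not np.allclose(np.diag(R), 1.0, atol=_ATOL):
        raise GenerationError("population matrix diagonal deviates from 1")
    eigmin = float(np.linalg.eigvalsh(R)[0])
    if eigmin <= 0.0:
        raise GenerationError(
            f"population matrix not positive definite (min eigenvalue {eigmin:.3e})"
        )
    return PopulationModel(
        spec=spec, Lambda_major=Lam, Lambda_minor=W, Phi=Phi,
        psi=psi, R=R, h2_major=h2_major, h2_minor=h2_minor,
    )
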