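"""Eigenvalue-based factor-retention criteria.

All criteria operate on principal-component eigenvalues of the *full*
correlation matrix (unit diagonal), not the reduced matrix with
communalities — the convention under which each eigenvalue is the variance
explained by its component:

* Kaiser (EV): count of eigenvalues strictly greater than one.
* Acceleration factor (AF): the scree elbow located by the maximum second
  difference of the eigenvalue sequence; optionally capped by Kaiser (AFEV).
* Parallel analysis (PAM / PA95): observed eigenvalues compared
  sequentially against the mean or 95th percentile of eigenvalues from k
  datasets of pure noise pushed through the same analysis pipeline.
* Revised parallel analysis (RPA / RPAEV): the reference for the (m+1)th
  eigenvalue comes from data simulated under an m-component model fitted
  to the observed correlation matrix, not from zero-factor noise.
* Velicer's minimum average partial (MAP): the m minimizing the mean
  squared partial correlation after partialing out m components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arms import AnalysisArm
from .correlation import CorrelationEstimate, DegenerateColumnError, repair_psd
from .sampling import BinaryMatrix, SampleMatrix, draw_from_corr

__all__ = [
    "EigenSpectrum",
    "RetentionResult",
    "MapTrace",
    "CriterionFailure",
    "eigen_spectrum",
    "kaiser_count",
    "acceleration_factor",
    "combine_with_kaiser",
    "parallel_analysis",
    "revised_parallel_analysis",
    "map_statistic",
    "map_count",
]

_MAX_REDRAWS = 50


class CriterionFailure(RuntimeError):
    """A criterion could not produce a count (recorded as missing)."""


@dataclass
class EigenSpectrum:
    """Descending principal-component eigenvalues of a correlation matrix."""

    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class RetentionResult:
    criterion: str
    m_hat: int


@dataclass
class MapTrace:
    """The f_m sequence of Velicer's MAP, m = 0 .. J-2 (may be truncated)."""

    f: np.ndarray


def _as_matrix(R) -> np.ndarray:
    return R.R_hat if isinstance(R, CorrelationEstimate) else np.asarray(R, float)


def eigen_spectrum(R) -> EigenSpectrum:
    """Descending eigenvalues of a symmetric unit-diagonal matrix."""
    M = _as_matrix(R)
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    vals = np.linalg.eigvalsh(M)[::-1]
    return EigenSpectrum(values=vals)


def kaiser_count(s: EigenSpectrum) -> int:
    """Number of eigenvalues strictly greater than one."""
    return int(np.sum(s.values > 1.0))


def acceleration_factor(s: EigenSpectrum) -> int:
    """Scree elbow by the maximum second difference of the eigenvalues.

    af_i = e_{i+1} - 2 e_i + e_{i-1} is defined for i = 2 .. J-1 (1-based);
    the retained count is i* - 1 where i* is the *first* index attaining
    the maximum, so the result lies in [1, J-2].
    """
    e = s.values
    if len(e) < 3:
        raise ValueError("need at least 3 eigenvalues")
    af = e[2:] - 2.0 * e[1:-1] + e[:-2]  # af[j] is the 1-based index j+2
    return int(np.argmax(af)) + 1


def combine_with_kaiser(m_a: int, m_kaiser: int) -> int:
    """Cap a retention count by the Kaiser count (take the minimum)."""
    if m_a < 0 or m_kaiser < 0:
        raise ValueError("retention counts must be non-negative")
    return min(m_a, m_kaiser)


def _sequential_count(observed: np.ndarray, reference: np.ndarray) -> int:
    """Largest m with observed[i] > reference[i] for every i <= m."""
    keep = observed > reference
    if not keep[0]:
        return 0
    stops = np.flatnonzero(~keep)
    return int(stops[0]) if stops.size else len(observed)


def _arm_data(sample, arm: AnalysisArm) -> np.ndarray:
    """Observed data on the arm's scale (dichotomizing if still continuous)."""
    if isinstance(sample, BinaryMatrix):
        if not arm.is_binary:
            raise ValueError("binary data passed to the continuous arm")
        return np.asarray(sample.values, dtype=float)
    vals = sample.values if isinstance(sample, SampleMatrix) else np.asarray(sample, float)
    return arm.transform(vals)


def _batched_pearson_spectra(X: np.ndarray) -> np.ndarray:
    """Eigenvalues of the Pearson correlation matrix for a stack of datasets.

    X has shape (k, N, J); returns (k, J) descending eigenvalues.
    """
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = Xc.std(axis=1, keepdims=True)
    if np.any(sd == 0.0):
        raise DegenerateColumnError("constant column in comparison data")
    Z = Xc / sd
    n = X.shape[1]
    S = np.einsum("kni,knj->kij", Z, Z) / n
    return np.linalg.eigvalsh(S)[:, ::-1]


def _comparison_spectra(n_obs: int, n_items: int, arm: AnalysisArm, k: int,
                        rng: np.random.Generator,
                        R_implied: np.ndarray | None = None) -> np.ndarray:
    """Eigenvalue spectra of k comparison datasets pushed through the arm.

    Comparison data are standard-normal noise (traditional parallel
    analysis) or draws from a model-implied correlation matrix (revised
    variant).  The draws follow the arm pipeline — dichotomized at the
    arm's threshold and correlated with the arm's method — so the null
    reference matches the observed analysis.  Draws with a degenerate
    column are regenerated.
    """
    def draw() -> np.ndarray:
        if R_implied is None:
            return rng.standard_normal((n_obs, n_items))
        return draw_from_corr(R_implied, n_obs, rng)

    if arm.corr_kind == "pearson":
        spectra = np.empty((k, n_items))
        done = 0
        tries = 0
        while done < k:
            batch = np.stack([arm.transform(draw()) for _ in range(k - done)])
            sd = batch.std(axis=1)
            good = np.flatnonzero(~np.any(sd == 0.0, axis=1))
            if good.size:
                spectra[done : done + good.size] = _batched_pearson_spectra(
                    batch[good]
                )
                done += good.size
            tries += 1
            if tries > _MAX_REDRAWS:
                raise CriterionFailure("comparison data degenerate repeatedly")
        return spectra

    spectra = np.empty((k, n_items))
    for i in range(k):
        for attempt in range(_MAX_REDRAWS):
            try:
                est = arm.correlation_of(arm.transform(draw()))
                break
            except DegenerateColumnError:
                continue
        else:
            raise CriterionFailure("comparison data degenerate repeatedly")
        spectra[i] = eigen_spectrum(est).values
    return spectra


def parallel_analysis(sample, arm: AnalysisArm, reference: str = "p95",
                      k: int = 100, rng: np.random.Generator | None = None,
                      observed: CorrelationEstimate | None = None) -> int:
    """Traditional parallel analysis with a mean or 95th-percentile reference.

    Retains the largest m such that every observed eigenvalue up to the
    m-th strictly exceeds its reference value (sequential stop at the
    first failure).  ``observed`` may carry a precomputed arm correlation
    estimate to avoid recomputation.
    """
    if reference not in ("mean", "p95"):
        raise ValueError("reference must be 'mean' or 'p95'")
    if k < 2:
        raise ValueError("need at least 2 comparison datasets")
    rng = rng if rng is not None else np.random.default_rng()
    data = _arm_data(sample, arm)
    n_obs, n_items = data.shape
    est = observed if observed is not None else arm.correlation_of(data)
    e_obs = eigen_spectrum(est).values
    spectra = _comparison_spectra(n_obs, n_items, arm, k, rng)
    if reference == "mean":
        ref = spectra.mean(axis=0)
    else:
        ref = np.quantile(spectra, 0.95, axis=0)
    return _sequential_count(e_obs, ref)


def _implied_pca_matrix(R_obs: np.ndarray, m: int,
                        construction: str = "unit_error") -> np.ndarray:
    """Correlation matrix implied by the first m principal components.

    Component loadings are U_m diag(d_m)**0.5 from the observed spectrum;
    m = 0 is the identity (pure standard-normal noise).

    ``unit_error`` (default): comparison data are the m components plus
    *standard-normal* errors, i.e. the population covariance is
    ``L_m L_m' + I`` standardized to a correlation matrix.  This extends
    the traditional parallel-analysis null — completely random standard
    normals — to an m-component null, and reduces to it exactly at m = 0.

    ``diag_reset``: the outer product ``L_m L_m'`` with the diagonal reset
    to one (residual variance = 1 - component communality), PSD-repaired
    if the reset pushed it indefinite.  This null carries far less residual
    variance, which makes the sequential test keep passing in data whose
    residual structure is non-trivial (it over-extracts heavily when minor
    factors are present).
    """
    J = R_obs.shape[0]
    if m == 0:
        return np.eye(J)
    d, U = np.linalg.eigh(R_obs)
    d, U = d[::-1], U[:, ::-1]
    lam = U[:, :m] * np.sqrt(np.clip(d[:m], 0.0, None))
    implied = lam @ lam.T
    if construction == "unit_error":
        implied = implied + np.eye(J)
        s = 1.0 / np.sqrt(np.diag(implied))
        return implied * s[:, None] * s[None, :]
    if construction == "diag_reset":
        np.fill_diagonal(implied, 1.0)
        return repair_psd(implied).R_hat
    raise ValueError(f"unknown implied-matrix construction {construction!r}")


def revised_parallel_analysis(sample, arm: AnalysisArm, k: int = 100,
                              with_kaiser: bool = False,
                              rng: np.random.Generator | None = None,
                              observed: CorrelationEstimate | None = None,
                              construction: str = "unit_error") -> int:
    """Revised parallel analysis (95th-percentile reference, PCA basis).

    Sequentially tests m = 0, 1, 2, ...: the (m+1)th observed eigenvalue
    is compared with the 95th percentile of (m+1)th eigenvalues from k
    datasets generated under the m-component model fitted to the observed
    correlation matrix.  The m = 0 stage draws from the identity and is
    therefore the traditional PA95 test of the first eigenvalue.  With
    ``with_kaiser`` a factor must additionally have an observed eigenvalue
    above one.
    """
    if k < 2:
        raise ValueError("need at least 2 comparison datasets")
    rng = rng if rng is not None else np.random.default_rng()
    data = _arm_data(sample, arm)
    n_obs, n_items = data.shape
    est = observed if observed is not None else arm.correlation_of(data)
    R_obs = est.R_hat
    e_obs = eigen_spectrum(est).values
    m = 0
    while m < n_items:
        if with_kaiser and not (e_obs[m] > 1.0):
            break
        implied = _implied_pca_matrix(R_obs, m, construction) if m > 0 else None
        spectra = _comparison_spectra(n_obs, n_items, arm, k, rng,
                                      R_implied=implied)
        q95 = np.quantile(spectra[:, m], 0.95)
        if not (e_obs[m] > q95):
            break
        m += 1
    return m


def _pca_loadings(R: np.ndarray, m: int) -> np.ndarray:
    d, U = np.linalg.eigh(R)
    d, U = d[::-1], U[:, ::-1]
    return U[:, :m] * np.sqrt(np.clip(d[:m], 0.0, None))


def map_statistic(R, m: int) -> float:
    """Velicer's f_m: mean squared off-diagonal partial correlation after
    partialing out the first m principal components (f_0 uses R itself)."""
    M = _as_matrix(R)
    J = M.shape[0]
    if not (0 <= m <= J - 2):
        raise ValueError("m must lie in [0, J-2]")
    if m == 0:
        A = M
    else:
        lam = _pca_loadings(M, m)
        A = M - lam @ lam.T
        diag = np.diag(A).copy()
        if np.any(diag <= 1e-10):
            raise CriterionFailure(f"degenerate partial covariance at m={m}")
        scale = 1.0 / np.sqrt(diag)
        A = A * scale[:, None] * scale[None, :]
    off = A[~np.eye(J, dtype=bool)]
    return float(np.mean(off ** 2))


def map_trace(R) -> MapTrace:
    """The f_m sequence for m = 0 .. J-2, truncated at a degenerate stage."""
    M = _as_matrix(R)
    J = M.shape[0]
    fs = []
    for m in range(0, J - 1):
        try:
            fs.append(map_statistic(M, m))
        except CriterionFailure:
            break
    return MapTrace(f=np.array(fs))


def map_count(R) -> int:
    """MAP retention count: argmin_m f_m over m >= 1, or 0 if f_1 >= f_0."""
    trace = map_trace(R)
    f = trace.f
    if len(f) < 2 or f[1] >= f[0]:
        return 0
    return int(np.argmin(f[1:])) + 1
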