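"""Model/Results interface for applying all retention criteria to one dataset.

``FactorRetention`` is constructed from a data matrix (continuous or
binary) plus the analysis choices — threshold and correlation kind — and
``fit`` evaluates the requested retention criteria, returning a
``FactorRetentionResults`` with the counts, the eigenvalue spectrum, the
correlation estimate, and a printable summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import criteria as crit
from .arms import ARMS, AnalysisArm
from .correlation import CorrelationEstimate
from .ega import ega_count
from .sampling import BinaryMatrix, SampleMatrix

__all__ = ["FactorRetention", "FactorRetentionResults", "CRITERIA",
           "evaluate_criterion"]

#: canonical criterion order used in reports
CRITERIA = ["EV", "AF", "AFEV", "PAM", "PA95", "RPA", "RPAEV", "MAP", "EGA"]


def evaluate_criterion(name: str, sample, arm: AnalysisArm,
                       rng: np.random.Generator, k: int = 100,
                       observed: CorrelationEstimate | None = None
                       ) -> crit.RetentionResult:
    """Uniform entry point: criterion(sample, arm, rng) -> RetentionResult.

    ``observed`` optionally carries the precomputed arm correlation so the
    deterministic criteria do not recompute it.
    """
    est = observed
    if est is None and name not in ("EGA",):
        est = arm.correlation_of(crit._arm_data(sample, arm))

    if name in ("EV", "AF", "AFEV", "MAP"):
        spec = crit.eigen_spectrum(est)
        if name == "EV":
            m = crit.kaiser_count(spec)
        elif name == "AF":
            m = crit.acceleration_factor(spec)
        elif name == "AFEV":
            m = crit.combine_with_kaiser(crit.acceleration_factor(spec),
                                         crit.kaiser_count(spec))
        else:
            m = crit.map_count(est)
    elif name in ("PAM", "PA95"):
        m = crit.parallel_analysis(sample, arm,
                                   reference="mean" if name == "PAM" else "p95",
                                   k=k, rng=rng, observed=est)
    elif name in ("RPA", "RPAEV"):
        m = crit.revised_parallel_analysis(sample, arm, k=k,
                                           with_kaiser=(name == "RPAEV"),
                                           rng=rng, observed=est)
    elif name == "EGA":
        m = ega_count(sample, arm, rng=rng)
    else:
        raise ValueError(f"unknown criterion {name!r}")
    return crit.RetentionResult(criterion=name, m_hat=int(m))


class FactorRetention:
    """How many factors underlie a data matrix, by nine retention criteria.

    Parameters
    ----------
    data : array-like, SampleMatrix or BinaryMatrix
        Observations in rows, items in columns.  Binary 0/1 data are
        analyzed as-is; continuous data may additionally be dichotomized
        by passing ``delta``.
    corr : {"pearson", "tetrachoric"}
        Correlation estimator for the analysis.
    delta : float, optional
        Dichotomization threshold applied to continuous data before
        analysis; leave None to analyze continuous values directly.
    """

    def __init__(self, data, corr: str = "pearson", delta: float | None = None):
        if isinstance(data, (SampleMatrix, BinaryMatrix)):
            self.sample = data
            binary = isinstance(data, BinaryMatrix)
            if binary and delta is not None:
                raise ValueError("data are already dichotomized")
            if not binary and delta is not None:
                from .sampling import dichotomize
                self.sample = dichotomize(data, delta)
                binary = True
        else:
            arr = np.asarray(data, dtype=float)
            if delta is not None:
                self.sample = BinaryMatrix((arr > delta).astype(np.int8),
                                           delta=float(delta))
                binary = True
            else:
                uniq = np.unique(arr)
                binary = uniq.size <= 2 and np.all(np.isin(uniq, (0.0, 1.0)))
                self.sample = (BinaryMatrix(arr.astype(np.int8), delta=np.nan)
                               if binary else SampleMatrix(arr))
        if corr == "tetrachoric" and not binary:
            raise ValueError("tetrachoric correlations require binary data")
        d = getattr(self.sample, "delta", None)
        self.arm = AnalysisArm(id="custom", delta=d if binary else None,
                               corr_kind=corr)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "FactorRetention":
        return cls(df.to_numpy(), **kwargs)

    def fit(self, criteria=None, k: int = 100, seed=None) -> "FactorRetentionResults":
        """Evaluate retention criteria; ``seed`` fixes the comparison draws."""
        names = list(criteria) if criteria is not None else list(CRITERIA)
        rng = np.random.default_rng(seed)
        observed = self.arm.correlation_of(
            crit._arm_data(self.sample, self.arm))
        counts = {}
        for name in names:
            sub = np.random.default_rng(rng.integers(0, 2**31))
            counts[name] = evaluate_criterion(
                name, self.sample, self.arm, sub, k=k, observed=observed
            ).m_hat
        return FactorRetentionResults(model=self, counts=counts,
                                      corr=observed)


@dataclass
class FactorRetentionResults:
    """Retention counts per criterion for one dataset."""

    model: FactorRetention
    counts: dict
    corr: CorrelationEstimate

    @property
    def spectrum(self) -> np.ndarray:
        return crit.eigen_spectrum(self.corr).values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"criterion": list(self.counts), "m_hat": list(self.counts.values())}
        )

    def summary(self) -> str:
        sample = self.model.sample
        kind = self.corr.kind
        lines = [
            "Factor retention summary",
            "========================",
            f"observations: {sample.n_obs}   items: {sample.n_items}   "
            f"correlations: {kind}"
            + (f"   threshold: {sample.delta:g}"
               if isinstance(sample, BinaryMatrix) and np.isfinite(sample.delta)
               else ""),
            f"repaired correlation matrix: {self.corr.repaired}",
            "",
            "criterion   retained",
            "--------------------",
        ]
        for name, m in self.counts.items():
            lines.append(f"{name:<12}{m:>8d}")
        top = ", ".join(f"{v:.3f}" for v in self.spectrum[:5])
        lines += ["", f"leading eigenvalues: {top}"]
        return "\n".join(lines)
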