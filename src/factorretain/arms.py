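"""Analysis arms: how a continuous draw is turned into a correlation matrix.

Each sample in the study is analyzed five ways: as continuous data with
Pearson correlations, and after dichotomization at an even (50-50) or a
skewed (75-25) split, each with Pearson and with tetrachoric correlations.
An arm bundles the threshold and the correlation kind so that observed
data and any criterion-internal comparison data (parallel-analysis null
draws, model-implied draws, the unidimensionality block in EGA) pass
through exactly the same pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlation import CorrelationEstimate, pearson_matrix, tetrachoric_matrix
from .sampling import DELTA_50_50, DELTA_75_25

__all__ = ["AnalysisArm", "ARMS", "ARM_ORDER"]


@dataclass(frozen=True)
class AnalysisArm:
    id: str
    delta: float | None      # None = analyze the continuous values directly
    corr_kind: str           # "pearson" | "tetrachoric"

    def __post_init__(self):
        if self.delta is None and self.corr_kind != "pearson":
            raise ValueError("the continuous arm uses Pearson correlations")

    @property
    def is_binary(self) -> bool:
        return self.delta is not None

    def transform(self, Z: np.ndarray) -> np.ndarray:
        """Apply the arm's dichotomization (if any) to continuous values."""
        Z = np.asarray(Z, dtype=float)
        if self.delta is None:
            return Z
        return (Z > self.delta).astype(float)

    def correlation_of(self, data: np.ndarray) -> CorrelationEstimate:
        """Correlation matrix of already arm-transformed data."""
        if self.corr_kind == "tetrachoric":
            return tetrachoric_matrix(data)
        return pearson_matrix(data)

    def correlation_of_continuous(self, Z: np.ndarray) -> CorrelationEstimate:
        """Full pipeline: transform continuous values, then correlate."""
        return self.correlation_of(self.transform(Z))


ARMS = {
    "cont_pearson": AnalysisArm("cont_pearson", None, "pearson"),
    "d50_pearson": AnalysisArm("d50_pearson", DELTA_50_50, "pearson"),
    "d50_tetra": AnalysisArm("d50_tetra", DELTA_50_50, "tetrachoric"),
    "d75_pearson": AnalysisArm("d75_pearson", DELTA_75_25, "pearson"),
    "d75_tetra": AnalysisArm("d75_tetra", DELTA_75_25, "tetrachoric"),
}

ARM_ORDER = ["cont_pearson", "d50_pearson", "d50_tetra", "d75_pearson", "d75_tetra"]
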