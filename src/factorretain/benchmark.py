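"""Desk-scale reproduction of single design cells.

``measure_cell`` recomputes one (criterion, communality, interfactor
correlation, N, arm) cell of the full design — population build, sampling,
arm pipeline, criterion — at a chosen replication count, using the same
hierarchical seed streams as :func:`factorretain.experiment.run_experiment`,
so a measured cell is exactly the corresponding slice of a full run.
"""

from __future__ import annotations

import numpy as np

from .arms import ARM_ORDER, ARMS
from .correlation import DegenerateColumnError
from .criteria import CriterionFailure, _arm_data
from .experiment import ExperimentConfig, build_scenario_grid
from .model import CRITERIA, evaluate_criterion
from .population import assemble_population
from .sampling import draw_continuous_sample

__all__ = ["measure_cell"]


def measure_cell(criterion: str, communality: str, theta: float, n_obs: int,
                 arm_id: str, reps: int, master_seed: int,
                 k: int = 100) -> dict:
    """Accuracy and mean bias of one criterion in one design cell.

    Returns a dict with ``accuracy`` (proportion of replications retaining
    exactly the true number of factors), ``mean_bias`` (mean retained minus
    true), ``n`` usable replications and the raw ``counts``.
    """
    config = ExperimentConfig(master_seed=master_seed, reps=reps,
                              k_comparison=k)
    cell = next(c for c in build_scenario_grid(config)
                if c.communality_level == communality
                and c.interfactor_corr == theta and c.n_obs == n_obs)
    model = assemble_population(cell.population_spec(config))
    arm = ARMS[arm_id]
    arm_i = ARM_ORDER.index(arm_id)
    crit_i = CRITERIA.index(criterion)
    m_true = config.n_true_factors
    counts = []
    for rep in range(reps):
        rng = np.random.default_rng(np.random.SeedSequence(
            master_seed, spawn_key=(1, cell.index, rep)))
        sample = draw_continuous_sample(model, n_obs, rng)
        sub = np.random.default_rng(np.random.SeedSequence(
            master_seed, spawn_key=(2, cell.index, rep, arm_i, crit_i)))
        try:
            observed = arm.correlation_of(_arm_data(sample, arm))
            counts.append(evaluate_criterion(
                criterion, sample, arm, sub, k=k, observed=observed).m_hat)
        except (CriterionFailure, DegenerateColumnError):
            continue
    counts = np.asarray(counts)
    return {
        "accuracy": float(np.mean(counts == m_true)),
        "mean_bias": float(np.mean(counts - m_true)),
        "n": int(counts.size),
        "counts": counts,
    }
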