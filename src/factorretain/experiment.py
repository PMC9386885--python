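"""The full Monte-Carlo design: 2 sample sizes x 2 interfactor correlations
x 2 communality ranges, five analysis arms, nine retention criteria.

Randomness is organized hierarchically from one master seed:

* stream (0, cell): the population draw for a cell — fixed across
  replications, so each condition has exactly one population matrix;
* stream (1, cell, rep): the continuous sample of a replication;
* stream (2, cell, rep, arm, criterion): comparison draws inside a
  criterion (parallel-analysis nulls, the EGA unidimensional block).

Criteria therefore never share randomness, parallel and serial execution
produce identical records, and any (cell, rep, arm, criterion) entry can
be recomputed in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .arms import ARMS, ARM_ORDER
from .correlation import DegenerateColumnError
from .criteria import CriterionFailure
from .model import CRITERIA, evaluate_criterion
from .population import PopulationSpec, assemble_population
from .sampling import draw_continuous_sample

__all__ = ["ExperimentConfig", "ScenarioCell", "build_scenario_grid",
           "run_trial", "run_experiment", "load_config"]

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["N", "theta", "communality", "arm", "rep", "criterion",
                  "m_hat", "correct", "bias", "status"]

COMMUNALITY_RANGES = {"low": (0.2, 0.3, 0.4), "high": (0.6, 0.7, 0.8)}


@dataclass(frozen=True)
class ExperimentConfig:
    """Design parameters; the defaults are the study conditions."""

    n_items: int = 20
    n_major: int = 3
    n_minor: int = 200
    common_ratio: float = 0.8
    sample_sizes: tuple = (100, 1000)
    interfactor_corrs: tuple = (0.0, 0.5)
    communality_levels: tuple = ("low", "high")
    reps: int = 1000
    k_comparison: int = 100
    arms: tuple = tuple(ARM_ORDER)
    criteria: tuple = tuple(CRITERIA)
    master_seed: int = 0

    @property
    def n_true_factors(self) -> int:
        return self.n_major

    @property
    def n_sample_draws(self) -> int:
        """Total continuous draws enumerated by the design."""
        n_cells = (len(self.sample_sizes) * len(self.interfactor_corrs)
                   * len(self.communality_levels))
        return n_cells * self.reps


@dataclass(frozen=True)
class ScenarioCell:
    index: int
    n_obs: int
    interfactor_corr: float
    communality_level: str
    population_seed: int

    def population_spec(self, config: ExperimentConfig) -> PopulationSpec:
        return PopulationSpec(
            n_items=config.n_items, n_major=config.n_major,
            n_minor=config.n_minor,
            communality_levels=COMMUNALITY_RANGES[self.communality_level],
            interfactor_corr=self.interfactor_corr,
            common_ratio=config.common_ratio, seed=self.population_seed,
        )


def _derived_seed(master_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % 2**31)


def build_scenario_grid(config: ExperimentConfig) -> list[ScenarioCell]:
    """The factorial grid of cells with deterministic population seeds."""
    cells = []
    idx = 0
    for level in config.communality_levels:
        for theta in config.interfactor_corrs:
            for n in config.sample_sizes:
                # population depends only on (level, theta): one matrix per
                # population condition, shared by both sample sizes
                pop_key = (config.communality_levels.index(level),
                           config.interfactor_corrs.index(theta))
                cells.append(ScenarioCell(
                    index=idx, n_obs=int(n), interfactor_corr=float(theta),
                    communality_level=level,
                    population_seed=_derived_seed(config.master_seed, 0, *pop_key),
                ))
                idx += 1
    return cells


def run_trial(cell: ScenarioCell, rep_index: int, master_seed: int,
              config: ExperimentConfig | None = None) -> list[dict]:
    """All (arm, criterion) records for one replication of one cell."""
    config = config or ExperimentConfig(master_seed=master_seed)
    model = assemble_population(cell.population_spec(config))
    m_true = config.n_true_factors
    rng = np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(1, cell.index, rep_index)))
    sample = draw_continuous_sample(model, cell.n_obs, rng)

    base = {"N": cell.n_obs, "theta": cell.interfactor_corr,
            "communality": cell.communality_level, "rep": rep_index}
    records = []
    for arm_i, arm_id in enumerate(config.arms):
        arm = ARMS[arm_id]
        try:
            from .criteria import _arm_data
            observed = arm.correlation_of(_arm_data(sample, arm))
        except DegenerateColumnError as exc:
            logger.warning("arm %s degenerate at rep %d: %s", arm_id,
                           rep_index, exc)
            observed = None
        for crit_i, name in enumerate(config.criteria):
            rec = dict(base, arm=arm_id, criterion=name)
            if observed is None:
                rec.update(m_hat=-1, correct=False, bias=0, status="missing")
                records.append(rec)
                continue
            sub = np.random.default_rng(np.random.SeedSequence(
                master_seed, spawn_key=(2, cell.index, rep_index, arm_i, crit_i)))
            try:
                m_hat = evaluate_criterion(name, sample, arm, sub,
                                           k=config.k_comparison,
                                           observed=observed).m_hat
                rec.update(m_hat=m_hat, correct=bool(m_hat == m_true),
                           bias=int(m_hat - m_true), status="ok")
            except (CriterionFailure, DegenerateColumnError) as exc:
                logger.warning("criterion %s failed (%s/%s rep %d): %s",
                               name, cell.index, arm_id, rep_index, exc)
                rec.update(m_hat=-1, correct=False, bias=0, status="missing")
            records.append(rec)
    return records


def run_experiment(config: ExperimentConfig, out_dir=None,
                   n_jobs: int = 1) -> pd.DataFrame:
    """Run the full design; returns (and optionally writes) the record table.

    With ``n_jobs > 1`` trials are distributed with joblib; because every
    trial owns its seed substreams the records are identical to a serial
    run (up to row order, which is re-sorted on assembly).
    """
    cells = build_scenario_grid(config)
    tasks = [(cell, rep) for cell in cells for rep in range(config.reps)]
    if n_jobs != 1:
        from joblib import Parallel, delayed
        chunks = Parallel(n_jobs=n_jobs)(
            delayed(run_trial)(cell, rep, config.master_seed, config)
            for cell, rep in tasks)
    else:
        chunks = [run_trial(cell, rep, config.master_seed, config)
                  for cell, rep in tasks]
    records = pd.DataFrame([r for chunk in chunks for r in chunk],
                           columns=RECORD_COLUMNS)
    records = records.sort_values(
        ["communality", "theta", "N", "arm", "rep", "criterion"],
        kind="mergesort").reset_index(drop=True)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        records.to_csv(out / "records.csv", index=False)
        manifest = {"config": _config_dict(config),
                    "n_cells": len(cells), "n_records": len(records)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return records


def _config_dict(config: ExperimentConfig) -> dict:
    d = asdict(config)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def load_config(path) -> ExperimentConfig:
    """Read an ExperimentConfig from a YAML or JSON file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    for key in ("sample_sizes", "interfactor_corrs", "communality_levels",
                "arms", "criteria"):
        if key in data:
            data[key] = tuple(data[key])
    return ExperimentConfig(**data)
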