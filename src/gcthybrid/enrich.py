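"""Mechanistic feature enrichment of clinical tables.

The core step of the hybrid pipeline: each patient's therapy trajectory
is simulated from their baseline tumor size and selected model variables
are sampled at fixed times and appended as new feature columns.  For
continuous cohorts the baseline is the first MRI volume; for categorical
cohorts each tertile group receives a shared random initial size and all
appended features are themselves tertile-coded.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .parameters import ModelConfig, ModelParameters
from .simulate import (DoseSchedule, SolverOptions, initial_state,
                       simulate_batch, tumor_burden)

__all__ = [
    "FeatureSpec",
    "tertile_discretize",
    "enrich_continuous",
    "enrich_categorical",
]

#: state variables exportable as features; "burden" is the total tumor
#: volume in cc, all others are raw model states
EXPORTABLE = ("burden", "Q", "G1", "I", "V", "C", "P", "PA", "PPAC", "Pe",
              "T", "TP", "TA")

DEFAULT_VARIABLES = ("burden", "I", "V", "C", "P", "PPAC", "T")


@dataclasses.dataclass(frozen=True)
class FeatureSpec:
    """Which model variables to export, and when.

    ``template`` formats the column names from the variable name and the
    sampling time in days.
    """

    variables: tuple[str, ...] = DEFAULT_VARIABLES
    times: tuple[float, ...] = (7.0, 14.0, 21.0)
    template: str = "model_{var}_t{time:g}"
    categorical: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.variables) - set(EXPORTABLE)
        if unknown:
            raise ValueError(f"unknown feature variable(s): {sorted(unknown)}")
        if any(t < 0 for t in self.times):
            raise ValueError("feature times must be nonnegative")

    def column_names(self) -> list[str]:
        return [self.template.format(var=v, time=t)
                for v in self.variables for t in self.times]


def tertile_discretize(values: Sequence[float]) -> np.ndarray:
    """Empirical tertile codes in {1, 2, 3}.

    Cuts at the 33.33% and 66.67% quantiles; values equal to a boundary
    go to the lower category, so a constant vector maps entirely to
    category 1.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot discretize an empty sequence")
    q1, q2 = np.quantile(v, [1 / 3, 2 / 3])
    return (1 + (v > q1).astype(int) + (v > q2).astype(int))


def _sample_features(traj, params: ModelParameters, spec: FeatureSpec,
                     ) -> np.ndarray:
    """Feature matrix (n_patients, n_vars * n_times) from a batch
    trajectory sampled exactly at spec.times."""
    cols = []
    for var in spec.variables:
        if var == "burden":
            vals = tumor_burden(traj.states, params, traj.layout)[1]
        else:
            vals = traj.value(var)
        cols.append(vals.T)          # (n_patients, n_times)
    return np.concatenate(cols, axis=1)


def _enrich_from_states(cohort: pd.DataFrame, states0: np.ndarray,
                        params, config, spec, schedule, options,
                        row_map: np.ndarray | None = None) -> pd.DataFrame:
    times = list(spec.times)
    if sorted(set(times)) != times:
        raise ValueError("feature times must be strictly increasing")
    horizon = max(schedule.horizon, max(times))
    schedule = dataclasses.replace(schedule, horizon=horizon)
    traj = simulate_batch(params, config, states0, schedule, times, options)
    feats = _sample_features(traj, params if isinstance(params, ModelParameters)
                             else params[0], spec)
    ok = np.all(np.isfinite(traj.states), axis=(0, 2)) & traj.success
    feats[~ok] = np.nan
    if row_map is not None:
        feats = feats[row_map]
        ok = ok[row_map]
    out = cohort.copy()
    for i, name in enumerate(spec.column_names()):
        out[name] = feats[:, i]
    out["model_sim_failed"] = (~ok).astype(int)
    return out


def enrich_continuous(cohort: pd.DataFrame, params: ModelParameters,
                      config: ModelConfig, spec: FeatureSpec,
                      schedule: DoseSchedule,
                      initial_mode: str = "residence_time",
                      options: SolverOptions | None = None) -> pd.DataFrame:
    """Append model features simulated from each patient's Volume1.

    The first MRI volume seeds the simulation (cc -> cells via
    ``cells_per_cc``); features are sampled at ``spec.times``.  Failed
    patients get NaN features and ``model_sim_failed`` = 1 instead of
    being dropped.  Purely deterministic.
    """
    if "Volume1" not in cohort.columns:
        raise ValueError("cohort table has no Volume1 column")
    if not spec.variables:
        return cohort.copy()
    v1 = cohort["Volume1"].to_numpy(dtype=float)
    states = np.stack([
        initial_state(v * params.cells_per_cc, initial_mode, params, config)
        for v in v1])
    return _enrich_from_states(cohort, states, params, config, spec,
                               schedule, options)


def enrich_categorical(cohort: pd.DataFrame, params: ModelParameters,
                       config: ModelConfig, spec: FeatureSpec,
                       schedule: DoseSchedule, seed: int,
                       per_patient: bool = False,
                       initial_mode: str = "residence_time",
                       options: SolverOptions | None = None) -> pd.DataFrame:
    """Append tertile-coded model features for a categorical cohort.

    Each size-category group receives one Uniform(0, 100) cc initial
    volume (shared within the group; ``per_patient=True`` draws one per
    patient instead), the model is solved, and every appended feature
    column is converted to tertile codes {1, 2, 3}.
    """
    if "SizeCategory" not in cohort.columns:
        raise ValueError("cohort table has no SizeCategory column")
    if not spec.variables:
        return cohort.copy()
    rng = np.random.default_rng(seed)
    cats = cohort["SizeCategory"].to_numpy()
    groups = np.unique(cats)
    if per_patient:
        v0 = rng.uniform(0.0, 100.0, size=len(cohort))
        states = np.stack([
            initial_state(v * params.cells_per_cc, initial_mode, params,
                          config) for v in v0])
        enriched = _enrich_from_states(cohort, states, params, config, spec,
                                       schedule, options)
    else:
        group_v0 = {g: rng.uniform(0.0, 100.0) for g in groups}
        states = np.stack([
            initial_state(group_v0[g] * params.cells_per_cc, initial_mode,
                          params, config) for g in groups])
        row_map = np.searchsorted(groups, cats)
        enriched = _enrich_from_states(cohort, states, params, config, spec,
                                       schedule, options, row_map=row_map)
    for name in spec.column_names():
        col = enriched[name].to_numpy(dtype=float)
        good = np.isfinite(col)
        codes = np.zeros(len(col), dtype=int)
        if good.any():
            codes[good] = tertile_discretize(col[good])
        enriched[name] = codes
    return enriched
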