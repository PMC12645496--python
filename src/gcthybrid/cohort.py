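"""Synthetic clinical cohorts with mechanistically generated tumor sizes.

The generator emulates the schema of four kinds of clinical tables: two
with continuous tumor volumes at 3 or 4 MRI time points and two with a
categorical (tertile-coded) tumor size.  Covariates (age, BMI, mutation
flags, lymph-node status, ethnicity, laterality) are drawn from simple
parametric marginals; each patient's tumor trajectory is produced by the
therapy ODE model, with covariates acting multiplicatively on selected
model parameters, and log-normal measurement noise applied to the
recorded volumes.  A hidden ground-truth side table retains the
per-patient parameters and pre-noise volumes so any patient can be
re-simulated exactly.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .enrich import tertile_discretize
from .parameters import ModelConfig, ModelParameters, default_parameters
from .sensitivity import BaselineProtocol
from .simulate import SolverOptions, initial_state, simulate_batch, tumor_burden

__all__ = [
    "CohortConfig",
    "CohortResult",
    "apply_covariate_effects",
    "generate_continuous_cohort",
    "generate_categorical_cohort",
    "DEFAULT_COVARIATE_EFFECTS",
]

log = logging.getLogger(__name__)

# How covariates act on the model: multiplicative factors applied to the
# named parameters when the covariate flag is 1.  Chosen so that positive
# nodal status and PIK3CA accelerate cycling while BRCA raises (and TP53
# blunts) the apoptotic response.
DEFAULT_COVARIATE_EFFECTS: dict[str, dict[str, float]] = {
    "lymph_node": {"a1": 1.2},
    "BRCA": {"d2": 1.15},
    "TP53": {"d2": 0.9},
    "PIK3CA": {"a2": 1.1},
}

MRI_GRID_4 = (0.0, 7.0, 14.0, 21.0)
MRI_GRID_3 = (0.0, 10.0, 21.0)

# A recorded volume can never fall below one tumor cell.
VOLUME_FLOOR_CC = 1e-9


@dataclasses.dataclass
class CohortConfig:
    """Settings of the synthetic-cohort generator.

    Volumes are in cc, times in days.  ``covariate_effects`` maps a binary
    covariate name to {parameter: multiplier}; prevalences are marginal
    Bernoulli probabilities.  The default time grids sample the 21-day
    treatment course weekly (4-point) or at {0, 10, 21} days (3-point).
    """

    n_patients: int = 500
    n_timepoints: int = 4
    time_grid: tuple[float, ...] | None = None
    prevalence: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"BRCA": 0.10, "TP53": 0.20,
                                 "PIK3CA": 0.15, "lymph_node": 0.30})
    ethnicity_probs: tuple[float, ...] = (0.70, 0.20, 0.10)
    age_mean: float = 55.0
    age_sd: float = 12.0
    age_range: tuple[float, float] = (18.0, 90.0)
    bmi_mean: float = 27.0
    bmi_sd: float = 5.0
    bmi_range: tuple[float, float] = (15.0, 50.0)
    covariate_effects: Mapping[str, Mapping[str, float]] = dataclasses.field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_COVARIATE_EFFECTS.items()})
    baseline_median_cc: float = 8.0
    baseline_log_sd: float = 0.5
    noise_log_sd: float = 0.1
    categorical: bool = False
    protocol: BaselineProtocol = dataclasses.field(
        default_factory=BaselineProtocol)
    initial_mode: str = "residence_time"
    seed: int = 0
    max_retries: int = 5

    def __post_init__(self) -> None:
        if self.n_timepoints not in (3, 4):
            raise ValueError("n_timepoints must be 3 or 4")
        if self.time_grid is None:
            self.time_grid = MRI_GRID_4 if self.n_timepoints == 4 else MRI_GRID_3
        if len(self.time_grid) != self.n_timepoints:
            raise ValueError("time_grid length must equal n_timepoints")
        for k, v in self.prevalence.items():
            if not 0 <= v <= 1:
                raise ValueError(f"prevalence[{k}] must lie in [0, 1]")
        for cov, eff in self.covariate_effects.items():
            for par, m in eff.items():
                if m <= 0:
                    raise ValueError(
                        f"multiplier {cov}->{par} must be positive")
        if self.noise_log_sd < 0:
            raise ValueError("noise_log_sd must be >= 0")

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["protocol"] = dataclasses.asdict(self.protocol)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "protocol" in data and isinstance(data["protocol"], dict):
            data["protocol"] = BaselineProtocol(**data["protocol"])
        if "time_grid" in data and data["time_grid"] is not None:
            data["time_grid"] = tuple(data["time_grid"])
        return cls(**data)


@dataclasses.dataclass
class CohortResult:
    """The observable table plus the hidden ground-truth side table."""

    table: pd.DataFrame
    truth: pd.DataFrame
    config: CohortConfig


def apply_covariate_effects(base_params: ModelParameters,
                            covariates: Mapping[str, int | bool],
                            effects: Mapping[str, Mapping[str, float]],
                            ) -> ModelParameters:
    """Per-patient parameters: base times the multiplier of every active
    binary covariate (multiplicative composition; deterministic)."""
    changes: dict[str, float] = {}
    for cov, par_mult in effects.items():
        if cov not in covariates:
            raise KeyError(f"covariate {cov!r} not present in patient record")
        if covariates[cov]:
            for par, mult in par_mult.items():
                changes[par] = changes.get(par, getattr(base_params, par)) * mult
    return base_params.replace(**changes) if changes else base_params


def _truncated_normal(rng, mean, sd, lo, hi, size):
    x = rng.normal(mean, sd, size)
    bad = (x < lo) | (x > hi)
    while bad.any():
        x[bad] = rng.normal(mean, sd, bad.sum())
        bad = (x < lo) | (x > hi)
    return x


def _draw_covariates(rng: np.random.Generator, cfg: CohortConfig,
                     n: int) -> pd.DataFrame:
    df = pd.DataFrame({
        "age": np.round(_truncated_normal(rng, cfg.age_mean, cfg.age_sd,
                                          *cfg.age_range, n), 1),
        "bmi": np.round(_truncated_normal(rng, cfg.bmi_mean, cfg.bmi_sd,
                                          *cfg.bmi_range, n), 1),
        "ethnicity": rng.choice(len(cfg.ethnicity_probs), size=n,
                                p=np.asarray(cfg.ethnicity_probs)
                                / np.sum(cfg.ethnicity_probs)),
        "laterality": rng.integers(0, 2, n),
    })
    for cov, prev in cfg.prevalence.items():
        df[cov] = (rng.random(n) < prev).astype(int)
    df["obesity"] = (df["bmi"] >= 30).astype(int)
    return df


def _simulate_volumes(base_params: ModelParameters, config: ModelConfig,
                      cfg: CohortConfig, covs: pd.DataFrame,
                      baseline_cc: np.ndarray,
                      options: SolverOptions | None = None) -> np.ndarray:
    """Pre-noise volumes (n, n_timepoints) for the given covariate table."""
    plist = [apply_covariate_effects(
        base_params, covs.iloc[i].to_dict(), cfg.covariate_effects)
        for i in range(len(covs))]
    states = np.stack([
        initial_state(v * base_params.cells_per_cc, cfg.initial_mode, pi, config)
        for v, pi in zip(baseline_cc, plist)])
    schedule = cfg.protocol.schedule(base_params)
    horizon = max(schedule.horizon, max(cfg.time_grid))
    schedule = dataclasses.replace(schedule, horizon=horizon)
    traj = simulate_batch(plist, config, states, schedule,
                          list(cfg.time_grid), options)
    if not traj.success:
        return np.full((len(covs), len(cfg.time_grid)), np.nan)
    vols = tumor_burden(traj.states, base_params, traj.layout)[1].T
    vols = np.where(np.isfinite(vols), vols, np.nan)
    return vols


def _generate(base_params: ModelParameters | None, config: ModelConfig | None,
              cfg: CohortConfig,
              options: SolverOptions | None = None) -> CohortResult:
    base_params = base_params or default_parameters()
    config = config or ModelConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients

    covs = _draw_covariates(rng, cfg, n)
    baseline = np.exp(np.log(cfg.baseline_median_cc)
                      + cfg.baseline_log_sd * rng.standard_normal(n))
    vols = _simulate_volumes(base_params, config, cfg, covs, baseline, options)

    # bounded per-patient retries on numerical failure
    for attempt in range(cfg.max_retries):
        bad = np.any(~np.isfinite(vols), axis=1)
        if not bad.any():
            break
        log.warning("regenerating %d failed patient(s), attempt %d",
                    bad.sum(), attempt + 1)
        covs.loc[bad, :] = _draw_covariates(rng, cfg, int(bad.sum())).values
        baseline[bad] = np.exp(np.log(cfg.baseline_median_cc)
                               + cfg.baseline_log_sd
                               * rng.standard_normal(int(bad.sum())))
        vols[bad] = _simulate_volumes(base_params, config, cfg,
                                      covs.loc[bad].reset_index(drop=True),
                                      baseline[bad], options)
    if np.any(~np.isfinite(vols)):
        raise RuntimeError("cohort generation failed after retries")

    vols = np.maximum(vols, VOLUME_FLOOR_CC)
    noise = np.exp(cfg.noise_log_sd * rng.standard_normal(vols.shape))
    observed = vols * noise

    table = covs.copy()
    table.insert(0, "id", np.arange(1, n + 1))
    truth = pd.DataFrame({"id": table["id"], "baseline_cc": baseline})
    plist = [apply_covariate_effects(
        base_params, covs.iloc[i].to_dict(), cfg.covariate_effects)
        for i in range(n)]
    affected = sorted({par for eff in cfg.covariate_effects.values()
                       for par in eff})
    for par in affected:
        truth[f"param_{par}"] = [getattr(pi, par) for pi in plist]
    for k in range(vols.shape[1]):
        truth[f"TrueVolume{k + 1}"] = vols[:, k]

    if cfg.categorical:
        latent_final = observed[:, -1]
        table["SizeCategory"] = tertile_discretize(latent_final)
        truth["LatentFinalVolume"] = latent_final
    else:
        for k in range(observed.shape[1]):
            table[f"Volume{k + 1}"] = observed[:, k]
    return CohortResult(table=table, truth=truth, config=cfg)


def generate_continuous_cohort(config_or_params=None, model_config=None,
                               cohort_config: CohortConfig | None = None,
                               options: SolverOptions | None = None,
                               ) -> CohortResult:
    """Cohort with continuous MRI volumes Volume1..VolumeK (K = 3 or 4).

    Accepts either ``generate_continuous_cohort(cohort_config)`` or the
    full ``(params, model_config, cohort_config)`` form.
    """
    if isinstance(config_or_params, CohortConfig):
        cohort_config = config_or_params
        config_or_params = None
    cfg = cohort_config or CohortConfig()
    if cfg.categorical:
        raise ValueError("categorical mode is on; use "
                         "generate_categorical_cohort")
    return _generate(config_or_params, model_config, cfg, options)


def generate_categorical_cohort(config_or_params=None, model_config=None,
                                cohort_config: CohortConfig | None = None,
                                options: SolverOptions | None = None,
                                ) -> CohortResult:
    """Cohort with a tertile-coded SizeCategory in {1, 2, 3} instead of
    continuous volumes; the latent volumes stay in the truth table."""
    if isinstance(config_or_params, CohortConfig):
        cohort_config = config_or_params
        config_or_params = None
    cfg = cohort_config or CohortConfig(categorical=True)
    if not cfg.categorical:
        cfg = dataclasses.replace(cfg, categorical=True)
    return _generate(config_or_params, model_config, cfg, options)
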