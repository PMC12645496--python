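"""Local one-at-a-time (OAT) parameter sensitivity of final tumor burden.

Each parameter is scaled by 1 + f for fractions f on a symmetric grid in
[-0.85, +0.85] while all others stay at baseline; the model is
re-simulated under the baseline treatment protocol and the day-21 total
tumor burden recorded.  A parameter's influence score is the largest
absolute relative change of the outcome over its grid, and parameters
are ranked by descending influence (alphabetical tie-break).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .parameters import ModelConfig, ModelParameters
from .simulate import (DoseSchedule, SolverOptions, build_schedule,
                       initial_state, simulate_batch, tumor_burden)

__all__ = [
    "BaselineProtocol",
    "SensitivityResult",
    "DEFAULT_SWEEP_PARAMETERS",
    "local_sensitivity",
    "rank_parameters",
    "results_to_frame",
]

# Every strictly positive rate/concentration/volume the right-hand side
# reads.  Excluded by design: j (integer compartment count), tau (enters
# only through the ktr = j/tau convention, not the dynamics), the bounded
# efficacies Emax_* and Psi (a +85% scaling leaves their admissible
# range), and the unit-scale conventions.
DEFAULT_SWEEP_PARAMETERS: tuple[str, ...] = (
    "a1", "a2", "d2", "d3", "ktr",
    "kappa", "delta", "alpha", "omega", "eta_half",
    "kp", "kQ", "ks", "psi_half", "kcp", "C_half", "gamma_P",
    "Cprod_star", "Cprod_max", "k_elim", "T_star",
    "ka", "V_PAC", "kep", "k12P", "k21P",
    "alpha_T", "kel", "kon", "R0", "k12", "k21", "V", "kint",
    "EC50_PAC", "EC50_TRAIL", "gamma_PAC", "gamma_TRAIL",
)


@dataclasses.dataclass(frozen=True)
class BaselineProtocol:
    """The reference treatment protocol for sensitivity sweeps: a daily
    oral PAC-1 course plus a single virus inoculum at t=0."""

    dose_mg: float = 375.0
    n_days: int = 21
    moi: float = 0.03
    tumor_cells: float = 1e9
    horizon: float = 21.0
    initial_mode: str = "residence_time"

    def schedule(self, params: ModelParameters) -> DoseSchedule:
        # dosing days beyond the horizon are dropped
        n_days = min(self.n_days, int(np.floor(self.horizon)) + 1)
        return build_schedule(self.dose_mg, n_days, self.moi,
                              self.tumor_cells, params,
                              horizon=self.horizon)


@dataclasses.dataclass
class SensitivityResult:
    parameter: str
    fractions: np.ndarray          # perturbation fractions, including 0
    outcomes: np.ndarray           # final tumor burden (cells) per fraction
    baseline: float                # outcome at fraction 0
    influence: float               # max |outcome - baseline| / baseline
    failed: np.ndarray             # per-fraction simulation-failure flags
    rank: int | None = None


def local_sensitivity(params: ModelParameters, config: ModelConfig,
                      protocol: BaselineProtocol | None = None,
                      parameter_list: Sequence[str] | None = None,
                      n_points: int = 9,
                      fraction_range: tuple[float, float] = (-0.85, 0.85),
                      options: SolverOptions | None = None,
                      ) -> list[SensitivityResult]:
    """One-at-a-time sweep of each parameter against final tumor burden.

    ``n_points`` must be odd and >= 3 so that fraction 0 lies on the grid;
    the baseline outcome is computed once and shared.  All perturbed
    simulations are stacked into a single vectorized solve.
    """
    if n_points < 3 or n_points % 2 == 0:
        raise ValueError("n_points must be an odd integer >= 3")
    protocol = protocol or BaselineProtocol()
    names = list(parameter_list if parameter_list is not None
                 else DEFAULT_SWEEP_PARAMETERS)
    base_dict = params.to_dict()
    for name in names:
        if name not in base_dict:
            raise KeyError(f"unknown parameter {name!r}")
        if name == "j":
            raise ValueError("the integer compartment count j cannot be "
                             "swept by fractional scaling")
    fractions = np.linspace(fraction_range[0], fraction_range[1], n_points)
    # snap the point nearest zero onto exactly zero (symmetric ranges
    # already contain it; asymmetric ones are snapped)
    i0 = int(np.argmin(np.abs(fractions)))
    fractions[i0] = 0.0

    schedule = protocol.schedule(params)
    t_eval = [0.0, protocol.horizon] if protocol.horizon > 0 else [0.0]

    jobs: list[tuple[str, float, ModelParameters]] = []
    for name in names:
        for f in fractions:
            pj = params if f == 0.0 else params.replace(
                **{name: base_dict[name] * (1.0 + f)})
            jobs.append((name, f, pj))
    jobs.append(("__baseline__", 0.0, params))

    states = np.stack([
        initial_state(protocol.tumor_cells, protocol.initial_mode, pj, config)
        for _, _, pj in jobs])
    traj = simulate_batch([pj for _, _, pj in jobs], config, states,
                          schedule, t_eval, options)
    final = traj.states[-1]                       # (B, n_state)
    cells = tumor_burden(final, params, traj.layout)[0]
    ok = np.all(np.isfinite(final), axis=1) & traj.success

    baseline = float(cells[-1])
    results = []
    for k, name in enumerate(names):
        sl = slice(k * n_points, (k + 1) * n_points)
        outc = np.asarray(cells[sl], dtype=float)
        failed = ~np.asarray(ok[sl])
        outc = np.where(failed, np.nan, outc)
        outc[fractions == 0.0] = baseline
        with np.errstate(invalid="ignore"):
            rel = np.abs(outc - baseline) / baseline
        influence = float(np.nanmax(rel)) if np.any(~np.isnan(rel)) else np.nan
        results.append(SensitivityResult(
            parameter=name, fractions=fractions.copy(), outcomes=outc,
            baseline=baseline, influence=influence, failed=failed))
    return rank_parameters(results)


def rank_parameters(results: list[SensitivityResult]) -> list[SensitivityResult]:
    """Order by descending influence; ties (and NaNs last) alphabetically.

    Returns the same result objects, sorted, with ``rank`` filled in
    (1 = most influential).
    """
    if not results:
        raise ValueError("no sensitivity results to rank")
    def key(r: SensitivityResult):
        inf = -np.inf if np.isnan(r.influence) else r.influence
        return (-inf, r.parameter)
    ordered = sorted(results, key=key)
    for i, r in enumerate(ordered, start=1):
        r.rank = i
    return ordered


def results_to_frame(results: list[SensitivityResult]):
    """Long-format table: one row per (parameter, fraction)."""
    import pandas as pd
    rows = []
    for r in results:
        for f, o, failed in zip(r.fractions, r.outcomes, r.failed):
            rows.append({"parameter": r.parameter, "fraction": f,
                         "outcome_cells": o, "influence": r.influence,
                         "rank": r.rank, "failed": bool(failed)})
    return pd.DataFrame(rows)


def plot_tornado(results: list[SensitivityResult], path, top: int = 15):
    """Horizontal-bar ranking of influence scores (log scale)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    sel = results[:top][::-1]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(sel) + 1.2))
    ax.barh([r.parameter for r in sel], [max(r.influence, 1e-300) for r in sel],
            color="#32618b")
    ax.set_xscale("log")
    ax.set_xlabel("influence: max |relative change| of final tumor burden")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
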