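"""Treatment schedules and numerical integration of the therapy model.

Dosing is impulsive: each oral PAC-1 dose adds its amount (ng) to the
gastrointestinal compartment PA, and the virus inoculum adds scaled
virion units to V, with the integration restarted at every event.  The
default integrator is adaptive explicit Runge–Kutta 4(5); a fixed-step
classical RK4 is available as an independent cross-check method.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model import StateLayout, immune_equilibrium, rhs, trail_equilibrium
from .parameters import ModelConfig, ModelParameters

__all__ = [
    "DoseEvent",
    "DoseSchedule",
    "SolverOptions",
    "Trajectory",
    "build_schedule",
    "initial_state",
    "simulate",
    "simulate_batch",
    "tumor_burden",
]

MG_TO_NG = 1e6


@dataclasses.dataclass(frozen=True)
class DoseEvent:
    time: float           # days
    target: str           # "PA_oral" (ng) or "V_inoculum" (scaled virions)
    amount: float

    def __post_init__(self) -> None:
        if self.target not in ("PA_oral", "V_inoculum"):
            raise ValueError(f"unknown dose target {self.target!r}")
        if self.amount < 0:
            raise ValueError("dose amount must be nonnegative")
        if self.time < 0:
            raise ValueError("dose time must be nonnegative")


@dataclasses.dataclass(frozen=True)
class DoseSchedule:
    """A sorted list of impulsive dose events over a fixed horizon (days)."""

    events: tuple[DoseEvent, ...]
    horizon: float

    def __post_init__(self) -> None:
        events = tuple(sorted(self.events, key=lambda e: e.time))
        object.__setattr__(self, "events", events)
        if self.horizon < 0:
            raise ValueError("horizon must be nonnegative")
        if events and events[-1].time > self.horizon:
            raise ValueError("dose events must lie within [0, horizon]")

    def to_json(self, path: str | Path) -> None:
        data = {"horizon": self.horizon,
                "events": [dataclasses.asdict(e) for e in self.events]}
        Path(path).write_text(json.dumps(data, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "DoseSchedule":
        data = json.loads(Path(path).read_text())
        return cls(events=tuple(DoseEvent(**e) for e in data["events"]),
                   horizon=float(data["horizon"]))


@dataclasses.dataclass(frozen=True)
class SolverOptions:
    """Integrator settings. ``method`` is a solve_ivp tag or "RK4" for the
    fixed-step classical scheme with step ``fixed_dt`` (days)."""

    rtol: float = 1e-6
    atol: float = 1e-9
    max_step: float = np.inf
    method: str = "RK45"
    fixed_dt: float = 1e-3

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be positive")
        if self.fixed_dt <= 0:
            raise ValueError("fixed_dt must be positive")


@dataclasses.dataclass
class Trajectory:
    """Sampled solution: times (nt,), states (nt, n_state) and diagnostics."""

    times: np.ndarray
    states: np.ndarray
    layout: StateLayout
    success: bool
    diagnostics: dict

    def value(self, name: str) -> np.ndarray:
        return self.states[..., self.layout.index[name]]

    def total_tumor(self) -> np.ndarray:
        return self.layout.total_tumor(self.states)

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.states, columns=list(self.layout.names))
        df.insert(0, "time", self.times)
        return df

    def to_tidy_csv(self, path: str | Path) -> None:
        df = self.to_frame().melt(id_vars="time", var_name="variable",
                                  value_name="value")
        df.to_csv(path, index=False)


def build_schedule(dose_mg: float, n_days: int, moi: float,
                   tumor_cells: float,
                   params: ModelParameters | None = None,
                   horizon: float | None = None) -> DoseSchedule:
    """Daily oral PAC-1 dosing plus a single t=0 virus inoculum.

    ``dose_mg`` mg is given once daily on days 0..n_days-1 (converted to
    ng); the inoculum is moi*tumor_cells virions, deposited at t=0 and
    expressed in scaled virion-units via ``cells_per_unit``.
    """
    if dose_mg < 0 or n_days < 0 or moi < 0 or tumor_cells < 0:
        raise ValueError("dose_mg, n_days, moi and tumor_cells must be >= 0")
    cells_per_unit = (params or _DEFAULTS()).cells_per_unit
    events = [DoseEvent(float(day), "PA_oral", dose_mg * MG_TO_NG)
              for day in range(int(n_days))]
    events.append(DoseEvent(0.0, "V_inoculum",
                            moi * tumor_cells / cells_per_unit))
    if horizon is None:
        horizon = max(float(n_days), 1.0)
    return DoseSchedule(events=tuple(events), horizon=float(horizon))


def _DEFAULTS() -> ModelParameters:
    from .parameters import default_parameters
    return default_parameters()


def initial_state(total_cells: float, mode: str, params: ModelParameters,
                  config: ModelConfig | None = None) -> np.ndarray:
    """Initial condition with the tumor split across cell-cycle compartments.

    ``all_quiescent`` puts the whole burden in Q; ``residence_time``
    distributes it proportionally to the mean residence times of the
    compartments (1/a1 for Q, 1/(a2+d2) for G1, 1/ktr for each of the j
    transit stages).  Immune, TRAIL and cytokine variables start at their
    drug-free equilibria; drug and virus compartments start at zero.
    """
    if total_cells < 0:
        raise ValueError("total_cells must be nonnegative")
    if config is None:
        config = ModelConfig()
    layout = StateLayout.for_config(params, config)
    y = layout.zeros()
    burden = total_cells / params.cells_per_unit
    if mode == "all_quiescent":
        y[layout.index["Q"]] = burden
        active = np.zeros(params.j)
    elif mode == "residence_time":
        w_q = 1.0 / params.a1
        w_g1 = 1.0 / (params.a2 + params.d2)
        w_a = 1.0 / params.ktr
        total_w = w_q + w_g1 + params.j * w_a
        y[layout.index["Q"]] = burden * w_q / total_w
        y[layout.index["G1"]] = burden * w_g1 / total_w
        active = np.full(params.j, burden * w_a / total_w)
    else:
        raise ValueError(f"unknown initial-state mode {mode!r}")
    y[layout.slice_A] = active
    c_star, p_star = immune_equilibrium(params)
    y[layout.index["C"]] = c_star
    y[layout.index["P"]] = p_star
    eq = trail_equilibrium(params)
    y[layout.index["T"]] = eq["T"]
    y[layout.index["TP"]] = eq["TP"]
    y[layout.index["TA"]] = eq["TA"]
    if config.variant_active_total == "ode_eq5":
        y[layout.index["N"]] = active.sum()
    return y


def _apply_events(y: np.ndarray, events: Iterable[DoseEvent],
                  layout: StateLayout) -> np.ndarray:
    y = y.copy()
    for ev in events:
        idx = layout.index["PA" if ev.target == "PA_oral" else "V"]
        y[..., idx] += ev.amount
    return y


def _rk4_segment(f: Callable, t0: float, t1: float, y0: np.ndarray,
                 sample_times: np.ndarray, dt: float):
    """Fixed-step classical RK4 over [t0, t1], stopping exactly on every
    sample time. Returns (samples, y_end, nfev)."""
    out = np.empty((len(sample_times),) + y0.shape)
    y = y0.copy()
    t = t0
    nfev = 0
    targets = list(sample_times)
    if not targets or targets[-1] < t1 - 1e-12:
        targets.append(t1)
    k = 0
    for target in targets:
        while t < target - 1e-12:
            h = min(dt, target - t)
            k1 = f(t, y)
            k2 = f(t + h / 2, y + h / 2 * k1)
            k3 = f(t + h / 2, y + h / 2 * k2)
            k4 = f(t + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
            nfev += 4
        if k < len(sample_times) and np.isclose(target, sample_times[k]):
            out[k] = y
            k += 1
    return out, y, nfev


def _integrate(params, config, layout, y0, schedule, t_eval, options,
               p_ns=None):
    """Event-segmented integration core.

    ``y0`` is the (possibly batched) state array; ``p_ns`` an optional
    namespace of per-batch parameter arrays.  A sample time that
    coincides with a dose event reports the post-dose state.
    """
    shape = y0.shape
    y0 = y0.reshape(-1)

    def f(t, y):
        dy = rhs(t, y.reshape(-1, layout.n_state), params, config,
                 layout=layout, _p=p_ns)
        return dy.reshape(-1)

    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval.ndim != 1 or np.any(np.diff(t_eval) <= 0):
        raise ValueError("t_eval must be strictly increasing")
    if len(t_eval) == 0:
        raise ValueError("t_eval must be nonempty")
    if t_eval[0] < 0 or t_eval[-1] > schedule.horizon + 1e-12:
        raise ValueError("t_eval must lie within [0, horizon]")

    t_end = float(t_eval[-1])
    event_times = sorted({e.time for e in schedule.events if e.time <= t_end})
    breaks = np.array(sorted({0.0, t_end, *event_times}))

    y = y0.astype(float).copy()
    out = np.empty((len(t_eval),) + y.shape)
    filled = np.zeros(len(t_eval), dtype=bool)
    nfev = 0
    success = True
    message = "ok"

    for i_seg in range(len(breaks)):
        seg_start = breaks[i_seg]
        seg_end = breaks[i_seg + 1] if i_seg + 1 < len(breaks) else seg_start
        evs = [e for e in schedule.events if np.isclose(e.time, seg_start)]
        if evs:
            y = _apply_events(y.reshape(-1, layout.n_state), evs,
                              layout).reshape(-1)
        # sample points exactly at the segment start (post-dose)
        at_start = ~filled & np.isclose(t_eval, seg_start)
        out[at_start] = y
        filled[at_start] = True
        if seg_end <= seg_start:
            continue
        mask = ~filled & (t_eval > seg_start) & (t_eval <= seg_end + 1e-12)
        seg_eval = t_eval[mask]
        if options.method == "RK4":
            seg_out, y, n = _rk4_segment(f, seg_start, seg_end, y,
                                         seg_eval, options.fixed_dt)
            nfev += n
            out[mask] = seg_out
            filled[mask] = True
        else:
            want = np.union1d(seg_eval, [seg_end])
            sol = solve_ivp(f, (seg_start, seg_end), y, method=options.method,
                            rtol=options.rtol, atol=options.atol,
                            max_step=options.max_step, t_eval=want)
            nfev += sol.nfev
            if not sol.success or not np.all(np.isfinite(sol.y)):
                success = False
                message = str(sol.message)
                break
            samples = sol.y.T
            sel = np.isin(want, seg_eval)
            out[mask] = samples[sel]
            filled[mask] = True
            y = samples[-1]

    if success and not filled.all():
        success = False
        message = "failed to sample all requested times"
    return out.reshape((len(t_eval),) + shape), nfev, success, message


def simulate(params: ModelParameters, config: ModelConfig,
             state0: np.ndarray, schedule: DoseSchedule,
             t_eval: Sequence[float],
             options: SolverOptions | None = None) -> Trajectory:
    """Integrate one patient under a dose schedule, sampled at ``t_eval``."""
    options = options or SolverOptions()
    layout = StateLayout.for_config(params, config)
    y0 = np.asarray(state0, dtype=float)
    if y0.shape != (layout.n_state,):
        raise ValueError(f"state0 must have shape ({layout.n_state},)")
    out, nfev, success, message = _integrate(
        params, config, layout, y0, schedule, t_eval, options)
    return Trajectory(times=np.asarray(t_eval, dtype=float), states=out,
                      layout=layout, success=success,
                      diagnostics={"nfev": nfev, "message": message,
                                   "method": options.method})


def _batch_namespace(params_list: Sequence[ModelParameters]):
    """Stack a list of parameter sets into an attribute namespace of
    per-patient arrays (or return the single set unchanged)."""
    import types
    fields = params_list[0].to_dict().keys()
    ns = types.SimpleNamespace()
    for f in fields:
        vals = np.array([getattr(p, f) for p in params_list], dtype=float)
        setattr(ns, f, vals[0].item() if np.all(vals == vals[0]) else vals)
    return ns


def simulate_batch(params_list: Sequence[ModelParameters] | ModelParameters,
                   config: ModelConfig, states0: np.ndarray,
                   schedule: DoseSchedule, t_eval: Sequence[float],
                   options: SolverOptions | None = None) -> Trajectory:
    """Integrate many independent patients in one stacked ODE solve.

    ``states0`` has shape (B, n_state); a list of per-patient parameter
    sets (identical ``j``) or a single shared set may be given.  Returns a
    Trajectory whose ``states`` has shape (nt, B, n_state).
    """
    options = options or SolverOptions()
    if isinstance(params_list, ModelParameters):
        base = params_list
        p_ns = None
    else:
        base = params_list[0]
        if any(p.j != base.j for p in params_list):
            raise ValueError("all patients must share the same j")
        ns = _batch_namespace(list(params_list))
        p_ns = ns
    layout = StateLayout.for_config(base, config)
    y0 = np.asarray(states0, dtype=float)
    if y0.ndim != 2 or y0.shape[1] != layout.n_state:
        raise ValueError(f"states0 must have shape (B, {layout.n_state})")
    out, nfev, success, message = _integrate(
        base, config, layout, y0, schedule, t_eval, options, p_ns=p_ns)
    return Trajectory(times=np.asarray(t_eval, dtype=float), states=out,
                      layout=layout, success=success,
                      diagnostics={"nfev": nfev, "message": message,
                                   "method": options.method})


def tumor_burden(state: np.ndarray, params: ModelParameters,
                 layout: StateLayout | None = None):
    """Total tumor burden of a state: (cells, volume in cc).

    cells = (Q + G1 + sum A_i) * cells_per_unit; volume = cells /
    cells_per_cc.  Works on single states or stacked arrays.
    """
    if layout is None:
        layout = StateLayout(params.j, include_n=(
            np.asarray(state).shape[-1] == 2 + params.j + 10 + 1))
    units = layout.total_tumor(np.asarray(state, dtype=float))
    cells = units * params.cells_per_unit
    return cells, cells / params.cells_per_cc
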