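"""Right-hand side of the tumor–virus–immune–drug ODE system.

State variables (all nonnegative):

======  =====================================================  ==========
symbol  meaning                                                units
======  =====================================================  ==========
Q       quiescent tumor cells                                  scaled cells
G1      tumor cells in the G1 phase                            scaled cells
A1..Aj  transit compartments of the active cell-cycle phases   scaled cells
I       virus-infected tumor cells                             scaled cells
V       free oncolytic virions                                 scaled virions
C       pro-inflammatory cytokine                              ng/ml
P       tumor-targeting phagocytes                             scaled cells
PA      PAC-1 amount in the gastrointestinal tract             ng
PPAC    PAC-1 plasma concentration                             ng/ml
Pe      PAC-1 peripheral concentration                         ng/ml
T       free TRAIL                                             ng/ml
TP      TRAIL–death-receptor complex                           ng/ml
TA      TRAIL in peripheral tissue (amount)                    ng
(N)     total active cells — integrated only in the ode_eq5
        variant, otherwise N = sum(A_i) algebraically
======  =====================================================  ==========

One scaled cell/virion unit equals ``cells_per_unit`` (default 1e10)
cells or virions.  The mitotic return doubles cells leaving the last
transit compartment (2*ktr*Aj into Q); the chain of j identical transit
stages gives the cell cycle an Erlang-distributed duration with mean
tau = j/ktr.

All functions accept scalars or arrays in their concentration/state
arguments; the right-hand side additionally accepts a batch of states
(shape ``(B, n_state)``) with per-batch parameter arrays, which is how
cohort-scale simulation is vectorized.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .parameters import ModelConfig, ModelParameters

__all__ = [
    "StateLayout",
    "pd_effect",
    "infection_hazard",
    "cytokine_production",
    "phagocyte_recruitment",
    "homeostatic_trail_production",
    "immune_equilibrium",
    "trail_equilibrium",
    "rhs",
]


class StateLayout:
    """Index map from state-variable names to positions in the flat vector."""

    def __init__(self, j: int, include_n: bool = False):
        self.j = int(j)
        self.include_n = bool(include_n)
        names = ["Q", "G1"] + [f"A{i}" for i in range(1, self.j + 1)]
        names += ["I", "V", "C", "P", "PA", "PPAC", "Pe", "T", "TP", "TA"]
        if include_n:
            names.append("N")
        self.names: tuple[str, ...] = tuple(names)
        self.index = {n: i for i, n in enumerate(names)}
        self.n_state = len(names)
        self.slice_A = slice(2, 2 + self.j)

    @classmethod
    def for_config(cls, params: ModelParameters, config: ModelConfig) -> "StateLayout":
        return cls(params.j, include_n=(config.variant_active_total == "ode_eq5"))

    def zeros(self) -> np.ndarray:
        return np.zeros(self.n_state)

    def pack(self, **values: float) -> np.ndarray:
        y = self.zeros()
        for k, v in values.items():
            y[self.index[k]] = v
        return y

    def unpack(self, y: np.ndarray) -> dict[str, float | np.ndarray]:
        return {n: y[..., i] for i, n in enumerate(self.names)}

    def total_tumor(self, y: np.ndarray) -> np.ndarray:
        """Q + G1 + sum(A_i) along the last axis (scaled cell-units)."""
        y = np.asarray(y)
        return y[..., 0] + y[..., 1] + y[..., self.slice_A].sum(axis=-1)


def _check_nonneg(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be nonnegative")
    return arr


def _hill(c, emax, ec50, gamma):
    c = np.asarray(c, dtype=float)
    cg = np.power(c, gamma)
    return emax * cg / (np.power(ec50, gamma) + cg)


def pd_effect(c_pac, c_trail, params: ModelParameters,
              config: ModelConfig | None = None):
    """Combined pharmacodynamic kill amplification E(c_PAC, c_TRAIL).

    Each drug contributes a Hill term E_x = Emax_x c^g / (EC50_x^g + c^g);
    the default combination adds an interaction term weighted by the
    potency Psi: E = E_P + E_T + Psi*E_P*E_T.  E multiplies the apoptotic
    rates as d2*(1+E) and d3*(1+E).
    """
    if config is None:
        config = ModelConfig()
    c_pac = _check_nonneg(c_pac, "c_pac")
    c_trail = _check_nonneg(c_trail, "c_trail")
    ep = _hill(c_pac, params.Emax_PAC, params.EC50_PAC, params.gamma_PAC)
    if config.pd_combination == "pac_only":
        return ep
    et = _hill(c_trail, params.Emax_TRAIL, params.EC50_TRAIL, params.gamma_TRAIL)
    if config.pd_combination == "bliss":
        return ep + et - ep * et
    return ep + et + params.Psi * ep * et


def infection_hazard(v, params: ModelParameters):
    """Per-cell infection rate kappa*V/(eta_half + V), 1/day.

    Mass-action contact saturating in the virion load with half-maximal
    effect at eta_half; bounded above by kappa.
    """
    v = _check_nonneg(v, "v")
    return params.kappa * v / (params.eta_half + v)


def cytokine_production(i_infected, params: ModelParameters):
    """Cytokine source Cprod(I), ng/ml/day.

    Rises from the homeostatic rate Cprod_star toward Cprod_max as the
    infected-cell pool grows, with half-effect at psi_half.
    """
    i = _check_nonneg(i_infected, "i_infected")
    return params.Cprod_star + (params.Cprod_max - params.Cprod_star) * i / (
        params.psi_half + i)


def phagocyte_recruitment(c, params: ModelParameters):
    """Cytokine-driven phagocyte recruitment phi(C) = kcp*C/(C_half + C)."""
    c = _check_nonneg(c, "c")
    return params.kcp * c / (params.C_half + c)


def homeostatic_trail_production(params: ModelParameters):
    """Constant TRAIL source Tprod (ng/ml/day) holding T at T_star.

    Derived so the tumor-free, dose-free TMDD subsystem has free TRAIL
    equilibrium T = T_star with the bound complex at its own steady state
    TP* = kon*R0*T*/(kint + kon*T*) and the peripheral exchange balanced:
    Tprod = kel*T* + kon*T**(R0 - TP*).
    """
    ts = params.T_star
    tp_star = params.kon * params.R0 * ts / (params.kint + params.kon * ts)
    return params.kel * ts + params.kon * ts * (params.R0 - tp_star)


def trail_equilibrium(params: ModelParameters) -> dict[str, float]:
    """Steady state (T, TP, TA) of the drug-free TRAIL subsystem."""
    ts = params.T_star
    tp_star = params.kon * params.R0 * ts / (params.kint + params.kon * ts)
    ta_star = params.k12 * params.V * ts / params.k21
    return {"T": ts, "TP": tp_star, "TA": ta_star}


def immune_equilibrium(params: ModelParameters) -> tuple[float, float]:
    """Infection-free steady state (C*, P*) of the cytokine–phagocyte pair.

    C* = Cprod_star / k_elim and P* = phi(C*) / gamma_P.
    """
    c_star = params.Cprod_star / params.k_elim
    p_star = float(phagocyte_recruitment(c_star, params)) / params.gamma_P
    return c_star, p_star


def rhs(t, state, params: ModelParameters, config: ModelConfig | None = None,
        layout: StateLayout | None = None, _p=None):
    """Time derivative of the full state.

    ``state`` may be a single vector (shape ``(n_state,)``) or a batch
    (shape ``(B, n_state)``); parameters may carry per-batch arrays via
    the private ``_p`` namespace used by the batch simulator.
    """
    p = _p if _p is not None else params
    if config is None:
        config = ModelConfig()
    y = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite state passed to rhs")
    single = y.ndim == 1
    if single:
        y = y[None, :]
    if layout is None:
        layout = StateLayout.for_config(params, config)
    if y.shape[-1] != layout.n_state:
        raise ValueError(
            f"state has {y.shape[-1]} components, layout expects {layout.n_state}")
    if config.clip_negative:
        y = np.maximum(y, 0.0)

    ix = layout.index
    j = layout.j
    Q = y[:, 0]
    G1 = y[:, 1]
    A = y[:, layout.slice_A]
    I = y[:, ix["I"]]
    V = y[:, ix["V"]]
    C = y[:, ix["C"]]
    P = y[:, ix["P"]]
    PA = y[:, ix["PA"]]
    PPAC = y[:, ix["PPAC"]]
    Pe = y[:, ix["Pe"]]
    T = y[:, ix["T"]]
    TP = y[:, ix["TP"]]
    TA = y[:, ix["TA"]]

    if config.variant_active_total == "ode_eq5":
        N = y[:, ix["N"]]
    else:
        N = A.sum(axis=1)

    # pharmacodynamic amplification and shared loss rates
    ep = _hill(PPAC, p.Emax_PAC, p.EC50_PAC, p.gamma_PAC)
    if config.pd_combination == "pac_only":
        E = ep
    else:
        et = _hill(T, p.Emax_TRAIL, p.EC50_TRAIL, p.gamma_TRAIL)
        if config.pd_combination == "bliss":
            E = ep + et - ep * et
        else:
            E = ep + et + p.Psi * ep * et
    h = p.kappa * V / (p.eta_half + V)          # per-cell infection hazard
    kill_Q = p.kp * P / (1.0 + p.kQ * Q)        # phagocyte kill, quiescent
    kill_G = p.kp * P / (1.0 + p.ks * G1)       # phagocyte kill, cycling
    loss_A = p.d3 * (1.0 + E) + h + kill_G      # common loss on A_i

    dy = np.empty_like(y)
    Aj = A[:, -1]
    dy[:, 0] = 2.0 * p.ktr * Aj - p.a1 * Q - kill_Q * Q
    dy[:, 1] = p.a1 * Q - (p.a2 + p.d2 * (1.0 + E) + h + kill_G) * G1

    entry_rate = p.a1 if config.variant_g1_entry == "literal_a1" else p.a2
    dy[:, 2] = entry_rate * G1 - p.ktr * A[:, 0] - loss_A * A[:, 0]
    for i in range(1, j):
        dy[:, 2 + i] = p.ktr * (A[:, i - 1] - A[:, i]) - loss_A * A[:, i]

    if config.variant_infection_sign == "literal_minus":
        target = G1 - N
    else:
        target = G1 + N
    dy[:, ix["I"]] = h * target - p.delta * I
    dy[:, ix["V"]] = p.alpha * p.delta * I - p.omega * V - h * target

    dy[:, ix["C"]] = (p.Cprod_star
                      + (p.Cprod_max - p.Cprod_star) * I / (p.psi_half + I)
                      - p.k_elim * C)
    dy[:, ix["P"]] = p.kcp * C / (p.C_half + C) - p.gamma_P * P

    dy[:, ix["PA"]] = -p.ka * PA
    dy[:, ix["PPAC"]] = (p.ka * PA / p.V_PAC
                         - (p.kep + p.k12P) * PPAC + p.k21P * Pe)
    dy[:, ix["Pe"]] = p.k12P * PPAC - p.k21P * Pe

    tp_star = p.kon * p.R0 * p.T_star / (p.kint + p.kon * p.T_star)
    tprod = p.kel * p.T_star + p.kon * p.T_star * (p.R0 - tp_star)
    dy[:, ix["T"]] = (p.alpha_T * p.delta * I - p.kel * T
                      - p.kon * T * (p.R0 - TP)
                      - p.k12 * T + p.k21 * TA / p.V + tprod)
    dy[:, ix["TP"]] = p.kon * (p.R0 - TP) * T - p.kint * TP
    dy[:, ix["TA"]] = p.k12 * p.V * T - p.k21 * TA

    if config.variant_active_total == "ode_eq5":
        dy[:, ix["N"]] = entry_rate * G1 - p.ktr * Aj - loss_A * N

    return dy[0] if single else dy
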