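"""Model parameters and structural configuration.

The tumor–virus–immune–drug model carries three groups of constants:

* cell-cycle and tumor–immune kinetics (rates in 1/day, cell pools in
  scaled units of ``cells_per_unit`` cells),
* pharmacokinetics of oral PAC-1 (two-compartment with first-order
  absorption) and of TRAIL (irreversible target-mediated drug
  disposition, TMDD),
* pharmacodynamics: Emax/Hill efficacies of PAC-1 and TRAIL and their
  interaction potency.

``ModelParameters`` holds every constant; ``ModelConfig`` selects between
structural variants of the right-hand side where the published system of
equations admits more than one reading (signs, entry rates, whether the
total active pool is integrated or defined algebraically).
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "ModelParameters",
    "ModelConfig",
    "default_parameters",
    "load_parameters",
    "save_parameters",
]

# Fields that are not strictly-positive rates/concentrations and therefore
# bypass the positivity check (j is integer >= 1; Psi may be 0).
_INT_FIELDS = {"j"}
_NONNEG_FIELDS = {"Psi"}


@dataclasses.dataclass(frozen=True)
class ModelParameters:
    """All rate constants, concentrations and unit-scale conventions.

    Units: rates 1/day; concentrations ng/ml; volumes ml; tumor-cell and
    phagocyte pools in scaled units of ``cells_per_unit`` cells; virions
    share the cell scale so an MOI maps directly onto cell counts.
    """

    # cell cycle
    a1: float      # quiescent -> G1 transition rate (1/day)
    a2: float      # G1 -> first active compartment rate (1/day)
    d2: float      # G1 apoptotic rate (1/day)
    d3: float      # active-phase apoptotic rate (1/day)
    ktr: float     # transit rate through active compartments (1/day)
    j: int         # number of transit (active-phase) compartments
    tau: float     # expected cell-cycle duration (days); ktr ~= j/tau
    # oncolytic virus
    kappa: float   # maximal per-cell infection rate (1/day)
    delta: float   # infected-cell lysis rate (1/day)
    alpha: float   # burst size (virions/cell)
    omega: float   # free-virion decay rate (1/day)
    eta_half: float  # virion half-saturation for infection (scaled virions)
    # innate immunity
    kp: float      # phagocyte-tumor contact kill rate (1/day)
    kQ: float      # digestion saturation constant for quiescent cells
    ks: float      # digestion saturation constant for cycling cells
    psi_half: float   # infected-cell half-effect for cytokine production
    kcp: float     # maximal phagocyte recruitment rate (scaled cells/day)
    C_half: float  # cytokine half-effect for phagocyte recruitment (ng/ml)
    gamma_P: float  # phagocyte death rate (1/day)
    Cprod_star: float  # homeostatic cytokine production (ng/ml/day)
    Cprod_max: float   # maximal cytokine production (ng/ml/day)
    k_elim: float      # cytokine elimination rate (1/day)
    # TRAIL homeostasis
    T_star: float  # homeostatic free-TRAIL concentration (ng/ml)
    # PAC-1 pharmacokinetics
    ka: float      # oral absorption rate (1/day)
    V_PAC: float   # PAC-1 volume of distribution (ml)
    kep: float     # plasma elimination rate (1/day)
    k12P: float    # plasma -> peripheral transfer (1/day)
    k21P: float    # peripheral -> plasma transfer (1/day)
    # TRAIL pharmacokinetics (irreversible TMDD)
    alpha_T: float  # TRAIL release per lysed scaled cell-unit (ng/ml)
    kel: float     # free-TRAIL elimination rate (1/day)
    kon: float     # TRAIL-receptor binding rate (1/day)
    R0: float      # total receptor pool (ng/ml equivalents)
    k12: float     # central -> peripheral TRAIL transfer (1/day)
    k21: float     # peripheral -> central TRAIL transfer (1/day)
    V: float       # TRAIL central-compartment volume (ml)
    kint: float    # bound-complex internalization rate (1/day)
    # pharmacodynamics
    Emax_PAC: float
    Emax_TRAIL: float
    gamma_PAC: float
    gamma_TRAIL: float
    Psi: float       # interaction potency weight, in [0, 1]
    EC50_PAC: float    # ng/ml
    EC50_TRAIL: float  # ng/ml
    # unit-scale conventions
    cells_per_unit: float = 1e10  # cells per scaled model unit
    cells_per_cc: float = 1e9     # cells per cm^3 of tumor volume

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name in _INT_FIELDS:
                if int(v) != v or v < 1:
                    raise ValueError(f"{f.name} must be an integer >= 1, got {v!r}")
                object.__setattr__(self, f.name, int(v))
            elif f.name in _NONNEG_FIELDS:
                if not 0 <= v:
                    raise ValueError(f"{f.name} must be >= 0, got {v!r}")
            else:
                if not v > 0:
                    raise ValueError(f"{f.name} must be > 0, got {v!r}")
        for name in ("Emax_PAC", "Emax_TRAIL"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v!r}")
        if not self.Psi <= 1:
            raise ValueError(f"Psi must lie in [0, 1], got {self.Psi!r}")

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def transit_consistency(self) -> float:
        """Relative mismatch |ktr - j/tau| / ktr of the transit chain."""
        return abs(self.ktr - self.j / self.tau) / self.ktr


_VARIANTS = {
    "variant_infection_sign": ("corrected_plus", "literal_minus"),
    "variant_g1_entry": ("text_a2", "literal_a1"),
    "variant_active_total": ("algebraic_sum", "ode_eq5"),
    "pd_combination": ("additive_synergy", "bliss", "pac_only"),
}


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Structural variants of the right-hand side.

    The published equations contain typographic inconsistencies; each flag
    selects between the literal reading and the corrected form implied by
    the accompanying text and by mass balance.  Defaults are the corrected
    forms.

    variant_infection_sign
        Target pool of infection: ``corrected_plus`` uses G1 + N (infection
        removes cycling cells), ``literal_minus`` uses G1 - N as printed.
    variant_g1_entry
        Rate of G1 -> A1 entry: ``text_a2`` (a2, consistent with the model
        description), ``literal_a1`` (a1 as printed).
    variant_active_total
        ``algebraic_sum`` defines the active pool N as sum(A_i) and does not
        integrate it; ``ode_eq5`` integrates a separate N equation.
    pd_combination
        Combined drug effect E from the PAC-1 and TRAIL Hill terms:
        ``additive_synergy`` E = E_P + E_T + Psi*E_P*E_T, ``bliss``
        independence, or ``pac_only``.
    clip_negative
        Project the state onto the nonnegative orthant before evaluating
        the right-hand side (the literal variants can cross zero).
    """

    variant_infection_sign: str = "corrected_plus"
    variant_g1_entry: str = "text_a2"
    variant_active_total: str = "algebraic_sum"
    pd_combination: str = "additive_synergy"
    clip_negative: bool = True

    def __post_init__(self) -> None:
        for name, allowed in _VARIANTS.items():
            v = getattr(self, name)
            if v not in allowed:
                raise ValueError(f"{name} must be one of {allowed}, got {v!r}")

    def replace(self, **changes) -> "ModelConfig":
        return dataclasses.replace(self, **changes)


def default_parameters() -> ModelParameters:
    """The bundled default parameter set."""
    text = resources.files("gcthybrid.data").joinpath(
        "default_parameters.json").read_text()
    return ModelParameters(**json.loads(text))


def load_parameters(path: str | Path) -> ModelParameters:
    """Load a parameter set from a JSON or YAML file.

    Keys absent from the file fall back to the bundled defaults; unknown
    keys raise.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"parameter file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(ModelParameters)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown parameter key(s) in {path}: {sorted(unknown)}")
    merged = default_parameters().to_dict()
    merged.update(data)
    return ModelParameters(**merged)


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write a parameter set as JSON or YAML depending on the suffix."""
    path = Path(path)
    data = params.to_dict()
    if path.suffix.lower() in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
    else:
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
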