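"""Core model definitions: parameters, states, flux equations.

All symbols use a fixed package-wide unit system: time in min, masses in
mg (acetaminophen), mmol (glucose) and μg (insulin), volumes in L, body
weight in kg.  Plasma concentrations follow from fixed volumes of
distribution per kg body weight (0.9 L/kg for acetaminophen, 0.251 L/kg
for glucose and insulin).

The five state masses are

* ``Ac_S`` / ``Ac_P`` — acetaminophen in stomach / plasma (mg)
* ``Gl_S`` / ``Gl_P`` — hexose in stomach / plasma glucose (mmol)
* ``In_P``            — plasma insulin (μg)

Gastric outflow is intermittent: a piecewise-constant schedule of codes
0/1/2 (:class:`ZSchedule`) selects a zero, slow (``k_SP2``) or fast
(``k_SP3``) first-order emptying rate.  Glucose disposal follows the
minimal-model form (glucose effectiveness plus an insulin-sensitivity
term driven by a time-lagged insulin signal); insulin secretion is a
Hill function of plasma glucose.  This module holds only pure algebra —
no integration logic.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ModelParameters",
    "ModelState",
    "Fluxes",
    "ZSchedule",
    "emptying_rate",
    "concentrations",
    "fluxes",
    "steady_state_k_In_UIn",
    "steady_state_iPGl_end",
    "apply_steady_state",
]

#: canonical parameter symbols accepted in config files / CLI overrides
PARAMETER_FIELDS = (
    "BW",
    "iAc_S",
    "iAc_P",
    "iGl_S",
    "iGl_P",
    "iIn_P",
    "iIs",
    "k_SP2",
    "k_SP3",
    "k_Ac_UAc",
    "k_Gl_UGl",
    "k_Is_UGl",
    "iPGl_end",
    "T_lag_SP",
    "T_lag_IS",
    "V_PIn",
    "K_Gl_PIn",
    "exp_PIn",
    "k_In_UIn",
    "vd_Ac",
    "vd_GlIn",
)


class ParameterError(ValueError):
    """Raised when a parameter set violates a model invariant."""


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of the aggregate model.

    Units follow the package convention (min, mg, mmol, μg, L, kg).
    ``vd_Ac`` and ``vd_GlIn`` are volume-of-distribution coefficients in
    L per kg body weight.
    """

    BW: float               # body weight, kg
    iAc_S: float            # oral acetaminophen dose, mg
    iAc_P: float            # basal plasma Ac mass, mg
    iGl_S: float            # meal hexose load entering stomach, mmol
    iGl_P: float            # basal plasma glucose mass, mmol
    iIn_P: float            # basal plasma insulin mass, μg
    iIs: float              # basal insulin signal, μg/L
    k_SP2: float            # slow gastric-emptying rate constant, 1/min
    k_SP3: float            # fast gastric-emptying rate constant, 1/min
    k_Ac_UAc: float         # first-order Ac elimination, 1/min
    k_Gl_UGl: float         # glucose effectiveness, L/min
    k_Is_UGl: float         # insulin sensitivity, L^2/(μg·min)
    iPGl_end: float         # zero-order endogenous glucose production, mmol/min
    T_lag_SP: float         # stomach-to-plasma glucose absorption lag, min
    T_lag_IS: float         # insulin-to-signal lag, min
    V_PIn: float            # maximal insulin secretion rate, μg/min
    K_Gl_PIn: float         # half-saturation glucose conc. of secretion, mM
    exp_PIn: float          # Hill coefficient of secretion, unitless
    k_In_UIn: float         # first-order insulin utilization, L/min
    vd_Ac: float = 0.9      # Ac volume of distribution, L/kg
    vd_GlIn: float = 0.251  # glucose/insulin volume of distribution, L/kg

    def __post_init__(self) -> None:
        if not self.BW > 0:
            raise ParameterError(f"BW must be > 0, got {self.BW}")
        if not self.K_Gl_PIn > 0:
            raise ParameterError(f"K_Gl_PIn must be > 0, got {self.K_Gl_PIn}")
        if self.exp_PIn < 1:
            raise ParameterError(f"exp_PIn must be >= 1, got {self.exp_PIn}")
        nonneg = (
            "iAc_S", "iAc_P", "iGl_S", "iGl_P", "iIn_P", "iIs",
            "k_SP2", "k_SP3", "k_Ac_UAc", "k_Gl_UGl", "k_Is_UGl",
            "iPGl_end", "T_lag_SP", "T_lag_IS", "V_PIn", "k_In_UIn",
            "vd_Ac", "vd_GlIn",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ParameterError(
                    f"{name} must be >= 0, got {getattr(self, name)}"
                )
        if self.k_SP3 < self.k_SP2:
            raise ParameterError(
                f"k_SP3 ({self.k_SP3}) must be >= k_SP2 ({self.k_SP2})"
            )

    # -- derived basal quantities ------------------------------------
    @property
    def v_plasma_glin(self) -> float:
        """Glucose/insulin plasma distribution volume, L."""
        return self.vd_GlIn * self.BW

    @property
    def v_plasma_ac(self) -> float:
        """Acetaminophen plasma distribution volume, L."""
        return self.vd_Ac * self.BW

    @property
    def basal_cGl_P(self) -> float:
        """Pre-meal plasma glucose concentration, mM."""
        return self.iGl_P / self.v_plasma_glin

    @property
    def basal_cIn_P(self) -> float:
        """Pre-meal plasma insulin concentration, μg/L."""
        return self.iIn_P / self.v_plasma_glin

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in PARAMETER_FIELDS}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        unknown = set(d) - set(PARAMETER_FIELDS)
        if unknown:
            raise ParameterError(
                f"unknown parameter keys {sorted(unknown)}; "
                f"valid keys are {list(PARAMETER_FIELDS)}"
            )
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class ModelState:
    """Instantaneous state: the five compartment masses at time ``t``."""

    t: float      # min since meal
    Ac_S: float   # mg
    Ac_P: float   # mg
    Gl_S: float   # mmol
    Gl_P: float   # mmol
    In_P: float   # μg

    def __post_init__(self) -> None:
        for name in ("Ac_S", "Ac_P", "Gl_S", "Gl_P", "In_P"):
            if getattr(self, name) < 0:
                raise ValueError(f"state mass {name} must be >= 0")

    @classmethod
    def initial(cls, params: ModelParameters) -> "ModelState":
        """Post-dose state at t=0: the meal and marker dose land in the
        stomach instantaneously."""
        return cls(
            t=0.0,
            Ac_S=params.iAc_S,
            Ac_P=params.iAc_P,
            Gl_S=params.iGl_S,
            Gl_P=params.iGl_P,
            In_P=params.iIn_P,
        )


@dataclass(frozen=True)
class Fluxes:
    """Instantaneous fluxes and concentrations at one evaluation point."""

    dAcS: float      # mg/min
    dAcP: float      # mg/min
    dGlS: float      # mmol/min
    PGl_ex: float    # exogenous glucose appearance, mmol/min
    PGl_end: float   # endogenous glucose production, mmol/min
    UGl: float       # glucose utilization, mmol/min
    PIn: float       # insulin secretion, μg/min
    UIn: float       # insulin utilization, μg/min
    Is: float        # insulin signal, μg/L
    cAc_P: float     # mg/L
    cGl_P: float     # mM
    cIn_P: float     # μg/L


class ZScheduleError(ValueError):
    pass


@dataclass(frozen=True)
class ZSchedule:
    """Piecewise-constant gastric-outflow code on half-open intervals.

    ``breakpoints`` are the interval edges starting at 0 (length n+1 for
    n intervals is allowed, or length n when only left edges are given —
    the last interval then extends to +inf).  ``values`` holds one code
    per interval: 0 = no outflow, 1 = slow (``k_SP2``), 2 = fast
    (``k_SP3``).  Lookup beyond the last breakpoint returns the last
    value; breakpoint ties resolve to the right-hand interval.
    """

    breakpoints: tuple = ()
    values: tuple = ()

    def __init__(self, breakpoints: Sequence[float], values: Sequence[int]):
        bp = tuple(float(b) for b in breakpoints)
        vals = tuple(int(v) for v in values)
        if len(bp) < 1 or bp[0] != 0.0:
            raise ZScheduleError("breakpoints must start at 0")
        if any(b1 >= b2 for b1, b2 in zip(bp, bp[1:])):
            raise ZScheduleError("breakpoints must be strictly increasing")
        if len(vals) not in (len(bp), len(bp) - 1):
            raise ZScheduleError(
                f"need one value per interval: {len(bp)} breakpoints "
                f"with {len(vals)} values"
            )
        for i, v in enumerate(vals):
            if v not in (0, 1, 2):
                raise ZScheduleError(
                    f"invalid Z code {v} in interval {i} "
                    f"(starting at t={bp[i]} min); codes must be 0, 1 or 2"
                )
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "values", vals)

    @property
    def n_intervals(self) -> int:
        return len(self.values)

    def interval_index(self, t: float) -> int:
        """Index of the interval containing time ``t`` (right-closed tie
        to the right-hand interval; clamped to the last interval)."""
        idx = int(np.searchsorted(np.asarray(self.breakpoints), t, side="right")) - 1
        return min(max(idx, 0), len(self.values) - 1)

    def code_at(self, t: float) -> int:
        return self.values[self.interval_index(t)]

    def rate_at(self, t: float, params: ModelParameters) -> float:
        return emptying_rate(self.code_at(t), params)

    def interval_rates(self, params: ModelParameters) -> np.ndarray:
        """Per-interval k_SP values as an array (for the integrator)."""
        return np.array([emptying_rate(v, params) for v in self.values])

    def left_edges(self) -> np.ndarray:
        return np.asarray(self.breakpoints[: len(self.values)], dtype=float)

    @classmethod
    def uniform(cls, codes: Sequence[int], spacing: float, start: float = 0.0) -> "ZSchedule":
        """Schedule on a uniform grid of ``spacing`` minutes."""
        n = len(codes)
        bp = [start + i * spacing for i in range(n + 1)]
        return cls(bp, codes)

    @classmethod
    def constant(cls, code: int) -> "ZSchedule":
        return cls([0.0], [code])


def emptying_rate(z_code: int, params: ModelParameters) -> float:
    """Map a Z code to its gastric-emptying rate constant (1/min)."""
    if z_code == 0:
        return 0.0
    if z_code == 1:
        return params.k_SP2
    if z_code == 2:
        return params.k_SP3
    raise ZScheduleError(f"invalid Z code {z_code}; codes must be 0, 1 or 2")


def concentrations(state: ModelState, params: ModelParameters):
    """Plasma concentrations (cAc_P mg/L, cGl_P mM, cIn_P μg/L)."""
    return (
        state.Ac_P / params.v_plasma_ac,
        state.Gl_P / params.v_plasma_glin,
        state.In_P / params.v_plasma_glin,
    )


def insulin_secretion(cGl_P: float, params: ModelParameters) -> float:
    """Hill-type pancreatic insulin secretion rate, μg/min.

    Continuous in cGl_P on [0, inf); the cGl_P -> 0 limit is 0.
    """
    if cGl_P <= 0.0:
        return 0.0
    ratio = params.K_Gl_PIn / cGl_P
    # guard float overflow in ratio**n (the limit of the flux is 0 anyway)
    if params.exp_PIn * math.log(ratio) > 700.0:
        return 0.0
    return params.V_PIn / (1.0 + ratio ** params.exp_PIn)


def fluxes(
    state: ModelState,
    z_code: int,
    lagged_PGl_ex: float,
    lagged_cIn_P: float,
    params: ModelParameters,
) -> Fluxes:
    """Evaluate all instantaneous fluxes at one state.

    The caller supplies the two history-dependent quantities: the gastric
    glucose outflow flux recorded ``T_lag_SP`` minutes earlier (which IS
    the exogenous appearance now) and the plasma insulin concentration
    recorded ``T_lag_IS`` minutes earlier (the insulin signal).  Before
    those lags have elapsed the conventions are PGl_ex = 0 and Is = iIs.
    """
    k_sp = emptying_rate(z_code, params)
    cAc_P, cGl_P, cIn_P = concentrations(state, params)

    dAcS = -k_sp * state.Ac_S
    dAcP = k_sp * state.Ac_S - params.k_Ac_UAc * state.Ac_P
    dGlS = -k_sp * state.Gl_S

    Is = lagged_cIn_P
    UGl = params.k_Gl_UGl * cGl_P + params.k_Is_UGl * Is * cGl_P
    PIn = insulin_secretion(cGl_P, params)
    UIn = params.k_In_UIn * cIn_P

    return Fluxes(
        dAcS=dAcS,
        dAcP=dAcP,
        dGlS=dGlS,
        PGl_ex=lagged_PGl_ex,
        PGl_end=params.iPGl_end,
        UGl=UGl,
        PIn=PIn,
        UIn=UIn,
        Is=Is,
        cAc_P=cAc_P,
        cGl_P=cGl_P,
        cIn_P=cIn_P,
    )


def steady_state_k_In_UIn(params: ModelParameters) -> float:
    """Insulin utilization constant that balances secretion at the basal
    state (makes dIn_P/dt vanish at t=0), L/min."""
    if params.iIn_P <= 0:
        raise ParameterError("iIn_P must be > 0 to derive k_In_UIn")
    c_in = params.basal_cIn_P
    c_gl = params.basal_cGl_P
    return params.V_PIn / c_in / (1.0 + (params.K_Gl_PIn / c_gl) ** params.exp_PIn)


def steady_state_iPGl_end(params: ModelParameters) -> float:
    """Endogenous glucose production that balances basal utilization
    (makes dGl_P/dt vanish at t=0 when PGl_ex=0), mmol/min."""
    c_gl = params.basal_cGl_P
    c_in = params.basal_cIn_P
    return params.k_Gl_UGl * c_gl + params.k_Is_UGl * c_in * c_gl


def apply_steady_state(params: ModelParameters) -> ModelParameters:
    """Return a copy with the pre-meal steady state enforced exactly:
    ``k_In_UIn`` and ``iPGl_end`` re-derived from the basal state, and
    ``iIs`` pinned to the basal insulin concentration."""
    return params.replace(
        k_In_UIn=steady_state_k_In_UIn(params),
        iPGl_end=steady_state_iPGl_end(params),
        iIs=params.basal_cIn_P,
    )
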