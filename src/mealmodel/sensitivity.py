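"""AUC sensitivity analysis: 0.5x-1.5x parameter perturbations.

Each parameter is set to 0.5x and 1.5x its reference value, the basal
steady-state constraints are re-derived, the model is simulated over the
420-min horizon, and the sensitivity coefficient

    SC = |AUC(1.5x) - AUC(0.5x)| / AUC(1.5x) / ((1.5 - 0.5) / 1.5)

is computed for the glucose and insulin curves (the fractional AUC
change per fractional parameter change).  "k_SP" is a single axis that
scales the slow and fast emptying constants jointly, preserving their
ratio.

Two under-determined conventions are exposed explicitly:

* ``auc_mode`` — "total" (default) or "incremental" area;
* ``steady_state`` — "always" (default: k_In_UIn, iPGl_end and iIs are
  re-derived from the basal state for every run, reference included) or
  "perturbed_only" (printed reference values are kept; constraints are
  re-derived only when a parameter they depend on is perturbed).
"""

from __future__ import annotations

from dataclasses import dataclass

from .model_core import (
    ModelParameters,
    ZSchedule,
    apply_steady_state,
    steady_state_iPGl_end,
    steady_state_k_In_UIn,
)
from .simulator import auc, simulate

__all__ = ["SENSITIVITY_PARAMETERS", "SensitivityResult", "coefficient",
           "sensitivity_coefficient", "table_of_coefficients"]


def coefficient(auc_low: float, auc_high: float,
                factor_low: float = 0.5, factor_high: float = 1.5) -> float:
    """Fractional AUC change per fractional parameter change (both
    normalized at the high setting); scale-invariant in the AUCs."""
    if auc_high == auc_low:
        return 0.0
    denom = (factor_high - factor_low) / factor_high
    return abs((auc_high - auc_low) / auc_high) / denom

SENSITIVITY_PARAMETERS = (
    "k_SP", "k_Gl_UGl", "k_Is_UGl", "T_lag_SP", "T_lag_IS",
    "V_PIn", "K_Gl_PIn", "exp_PIn",
)

#: parameters whose perturbation invalidates the basal insulin balance
_NEEDS_K_IN_UIN = {"V_PIn", "K_Gl_PIn", "exp_PIn"}
#: parameters whose perturbation invalidates the basal glucose balance
_NEEDS_IPGL_END = {"k_Gl_UGl", "k_Is_UGl"}


@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    sc_glucose: float
    sc_insulin: float
    auc_glucose_low: float    # mM·min at 0.5x
    auc_glucose_high: float   # mM·min at 1.5x
    auc_insulin_low: float    # μg/L·min at 0.5x
    auc_insulin_high: float   # μg/L·min at 1.5x
    auc_mode: str
    steady_state: str


def _perturbed(params: ModelParameters, name: str, factor: float,
               steady_state: str) -> ModelParameters:
    if name == "k_SP":
        p = params.replace(k_SP2=params.k_SP2 * factor,
                           k_SP3=params.k_SP3 * factor)
    else:
        p = params.replace(**{name: getattr(params, name) * factor})

    if steady_state == "always":
        return apply_steady_state(p)
    # perturbed_only: re-derive just the constraint the perturbation broke
    if name in _NEEDS_K_IN_UIN:
        p = p.replace(k_In_UIn=steady_state_k_In_UIn(p))
    if name in _NEEDS_IPGL_END:
        p = p.replace(iPGl_end=steady_state_iPGl_end(p))
    return p


def sensitivity_coefficient(
    name: str,
    params: ModelParameters,
    z: ZSchedule,
    auc_mode: str = "total",
    steady_state: str = "always",
    factor_low: float = 0.5,
    factor_high: float = 1.5,
    horizon: float = 420.0,
    dt: float = 0.002,
    report_every: float = 1.0,
    lag_convention: str = "outflow",
) -> SensitivityResult:
    """Sensitivity of the 420-min glucose and insulin AUCs to ``name``."""
    if name not in SENSITIVITY_PARAMETERS:
        raise ValueError(
            f"unknown sensitivity parameter {name!r}; valid names are "
            f"{list(SENSITIVITY_PARAMETERS)}"
        )
    if steady_state not in ("always", "perturbed_only"):
        raise ValueError(f"unknown steady_state convention {steady_state!r}")

    aucs = {}
    for label, factor in (("low", factor_low), ("high", factor_high)):
        p = _perturbed(params, name, factor, steady_state)
        traj = simulate(p, z, horizon=horizon, dt=dt,
                        report_every=report_every,
                        lag_convention=lag_convention)
        aucs[label] = {
            analyte: auc(traj, analyte, 0.0, horizon, mode=auc_mode)
            for analyte in ("glucose", "insulin")
        }

    def sc(analyte: str) -> float:
        return coefficient(aucs["low"][analyte], aucs["high"][analyte],
                           factor_low, factor_high)

    return SensitivityResult(
        parameter=name,
        sc_glucose=sc("glucose"),
        sc_insulin=sc("insulin"),
        auc_glucose_low=aucs["low"]["glucose"],
        auc_glucose_high=aucs["high"]["glucose"],
        auc_insulin_low=aucs["low"]["insulin"],
        auc_insulin_high=aucs["high"]["insulin"],
        auc_mode=auc_mode,
        steady_state=steady_state,
    )


def table_of_coefficients(
    params: ModelParameters,
    z: ZSchedule,
    auc_mode: str = "total",
    steady_state: str = "always",
    **kwargs,
) -> list[SensitivityResult]:
    """All 8 coefficients, sorted by glucose sensitivity (descending)."""
    rows = [
        sensitivity_coefficient(name, params, z, auc_mode=auc_mode,
                                steady_state=steady_state, **kwargs)
        for name in SENSITIVITY_PARAMETERS
    ]
    rows.sort(key=lambda r: r.sc_glucose, reverse=True)
    return rows
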