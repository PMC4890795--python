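"""Fixed-step integration of the delay system and trajectory summaries.

The integrator is 4th-order Runge-Kutta at a 0.002-min step by default
(reported every minute over a 420-min horizon).  The two fixed lags are
handled with history buffers at the integration step — see
:mod:`mealmodel._integrate` for the kernel and the lag conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._integrate import integrate
from .model_core import ModelParameters, ZSchedule

__all__ = ["Trajectory", "SimulationError", "simulate", "auc", "count_peaks"]

DEFAULT_HORIZON = 420.0   # min
DEFAULT_DT = 0.002        # min
DEFAULT_REPORT = 1.0      # min

_ANALYTES = {"acetaminophen": "cAc_P", "glucose": "cGl_P", "insulin": "cIn_P"}


class SimulationError(RuntimeError):
    """Raised when integration produces a negative state mass."""


@dataclass(frozen=True)
class Trajectory:
    """Dense simulated timecourse on a uniform reporting grid."""

    times: np.ndarray      # min
    Ac_S: np.ndarray       # mg
    Ac_P: np.ndarray       # mg
    Gl_S: np.ndarray       # mmol
    Gl_P: np.ndarray       # mmol
    In_P: np.ndarray       # μg
    cAc_P: np.ndarray      # mg/L
    cGl_P: np.ndarray      # mM
    cIn_P: np.ndarray      # μg/L
    PGl_ex: np.ndarray     # mmol/min, exogenous appearance at report times
    Is: np.ndarray         # μg/L, insulin signal at report times
    cum_PGl_ex: np.ndarray  # mmol, integrated exogenous appearance
    params: ModelParameters = None
    z: ZSchedule = None

    def concentration(self, analyte: str) -> np.ndarray:
        try:
            return getattr(self, _ANALYTES[analyte])
        except KeyError:
            raise KeyError(
                f"unknown analyte {analyte!r}; expected one of "
                f"{sorted(_ANALYTES)}"
            ) from None

    def sample(self, analyte: str, at_times) -> np.ndarray:
        """Concentration of ``analyte`` linearly interpolated at times."""
        return np.interp(np.asarray(at_times, dtype=float),
                         self.times, self.concentration(analyte))

    def to_frame(self) -> pd.DataFrame:
        """Tidy export (one row per reported time)."""
        return pd.DataFrame(
            {
                "time_min": self.times,
                "AcS_mg": self.Ac_S,
                "AcP_mg": self.Ac_P,
                "GlS_mmol": self.Gl_S,
                "GlP_mmol": self.Gl_P,
                "InP_ug": self.In_P,
                "cAcP_mg_per_L": self.cAc_P,
                "cGlP_mM": self.cGl_P,
                "cInP_ug_per_L": self.cIn_P,
            }
        )


def simulate(
    params: ModelParameters,
    z: ZSchedule,
    horizon: float = DEFAULT_HORIZON,
    dt: float = DEFAULT_DT,
    report_every: float = DEFAULT_REPORT,
    lag_convention: str = "outflow",
) -> Trajectory:
    """Integrate the model over ``[0, horizon]``.

    Parameters
    ----------
    params, z
        Parameter set and gastric-outflow schedule.
    horizon, dt, report_every
        Span, integration step and reporting spacing, all in minutes.
        ``report_every`` must be an integer multiple of ``dt``.
    lag_convention
        ``"outflow"`` (default) replays the gastric outflow flux with a
        pure transport delay; ``"stomach_mass"`` applies the current
        emptying rate to the lagged stomach mass.

    Raises
    ------
    SimulationError
        If a state mass goes negative (pathological parameter set);
        states are never clamped.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if horizon < 0:
        raise ValueError(f"horizon must be >= 0, got {horizon}")
    n_steps = int(round(horizon / dt))
    stride = int(round(report_every / dt))
    if stride < 1 or abs(stride * dt - report_every) > 1e-9 * max(1.0, report_every):
        raise ValueError(
            f"report_every ({report_every}) must be a positive integer "
            f"multiple of dt ({dt})"
        )
    try:
        conv = {"outflow": 0, "stomach_mass": 1}[lag_convention]
    except KeyError:
        raise ValueError(
            f"unknown lag_convention {lag_convention!r}; expected "
            "'outflow' or 'stomach_mass'"
        ) from None

    y0 = np.array(
        [params.iAc_S, params.iAc_P, params.iGl_S, params.iGl_P, params.iIn_P]
    )
    times, states, pglex, isig, ok = integrate(
        y0,
        n_steps,
        float(dt),
        stride,
        z.left_edges(),
        z.interval_rates(params),
        float(params.T_lag_SP),
        float(params.T_lag_IS),
        float(params.iIs),
        conv,
        params.v_plasma_glin,
        params.v_plasma_ac,
        params.k_Ac_UAc,
        params.k_Gl_UGl,
        params.k_Is_UGl,
        params.iPGl_end,
        params.V_PIn,
        params.K_Gl_PIn,
        float(params.exp_PIn),
        params.k_In_UIn,
    )
    if not ok:
        t_fail = times[-1] + dt if len(times) else 0.0
        raise SimulationError(
            f"state mass went negative near t={t_fail:.3f} min; "
            "the parameter set is pathological at this step size"
        )
    return Trajectory(
        times=times,
        Ac_S=states[:, 0],
        Ac_P=states[:, 1],
        Gl_S=states[:, 2],
        Gl_P=states[:, 3],
        In_P=states[:, 4],
        cAc_P=states[:, 1] / params.v_plasma_ac,
        cGl_P=states[:, 3] / params.v_plasma_glin,
        cIn_P=states[:, 4] / params.v_plasma_glin,
        PGl_ex=pglex,
        Is=isig,
        cum_PGl_ex=states[:, 5],
        params=params,
        z=z,
    )


def auc(
    traj: Trajectory,
    analyte: str,
    t0: float = 0.0,
    t1: float = DEFAULT_HORIZON,
    mode: str = "total",
) -> float:
    """Trapezoidal area under a concentration curve, concentration·min.

    ``mode="incremental"`` subtracts the t=0 concentration before
    integrating (the result may then be negative for curves that dip
    below baseline).
    """
    if mode not in ("total", "incremental"):
        raise ValueError(f"unknown AUC mode {mode!r}")
    c = traj.concentration(analyte)
    if not (t0 < t1):
        raise ValueError(f"need t0 < t1, got [{t0}, {t1}]")
    if t0 < traj.times[0] - 1e-9 or t1 > traj.times[-1] + 1e-9:
        raise ValueError(
            f"[{t0}, {t1}] outside trajectory span "
            f"[{traj.times[0]}, {traj.times[-1]}]"
        )
    # grid points strictly inside, plus interpolated endpoints
    inner = (traj.times > t0) & (traj.times < t1)
    tt = np.concatenate(([t0], traj.times[inner], [t1]))
    cc = np.concatenate(
        ([np.interp(t0, traj.times, c)], c[inner], [np.interp(t1, traj.times, c)])
    )
    if mode == "incremental":
        cc = cc - c[0]
    return float(np.trapezoid(cc, tt))


def count_peaks(values: np.ndarray, prominence: float) -> int:
    """Number of local maxima with at least the given prominence."""
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(np.asarray(values, dtype=float), prominence=prominence)
    return int(len(peaks))
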