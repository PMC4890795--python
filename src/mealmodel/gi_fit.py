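"""Differential-evolution estimation of the glucose-insulin parameters.

Eight parameters are free: k_Gl_UGl, k_Is_UGl, T_lag_SP, T_lag_IS,
V_PIn, K_Gl_PIn, exp_PIn and iIn_P.  The insulin utilization constant
and the endogenous glucose production are not free — they are re-derived
from each candidate through the basal steady-state constraints before
simulation, so every evaluated candidate starts from a steady pre-meal
state.  The marker-derived emptying rates and outflow schedule are held
fixed (the marker subsystem is fit first, separately).

The optimizer runs 80 candidate sets per generation for 200 generations;
the 30 best members of the final population yield the reported
mean ± SE per parameter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import differential_evolution

from .gastric_fit import Timecourse, rmspe
from .model_core import ModelParameters, ZSchedule, apply_steady_state
from .simulator import SimulationError, simulate

__all__ = ["FIT_PARAMETER_NAMES", "DEFAULT_BOUNDS", "GIFitConfig",
           "GIFitResult", "candidate_params", "objective", "fit"]

FIT_PARAMETER_NAMES = (
    "k_Gl_UGl", "k_Is_UGl", "T_lag_SP", "T_lag_IS",
    "V_PIn", "K_Gl_PIn", "exp_PIn", "iIn_P",
)

#: search box per free parameter (an order of magnitude around the
#: reference values; the method itself prescribes no bounds)
DEFAULT_BOUNDS = {
    "k_Gl_UGl": (0.0, 1e-3),     # L/min
    "k_Is_UGl": (0.0, 1.0),      # L^2/(μg·min)
    "T_lag_SP": (0.0, 120.0),    # min
    "T_lag_IS": (0.0, 120.0),    # min
    "V_PIn": (1e-6, 100.0),      # μg/min
    "K_Gl_PIn": (1e-6, 30.0),    # mM
    "exp_PIn": (1.0, 20.0),      # unitless
    "iIn_P": (1e-6, 50.0),       # μg
}


@dataclass(frozen=True)
class GIFitConfig:
    popsize: int = 80            # candidate sets per generation
    generations: int = 200
    elite: int = 30              # members retained for mean ± SE
    seed: int | None = None
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    # dithered mutation converges far deeper than a fixed factor within
    # the same 200 generations, which matters for the near-flat
    # glucose-effectiveness direction
    mutation: tuple = (0.5, 1.0)
    recombination: float = 0.9
    strategy: str = "best1bin"
    dt: float = 0.002            # integration step during fitting, min
    report_every: float = 1.0    # trajectory reporting spacing, min
    horizon: float = 420.0

    def __post_init__(self) -> None:
        if self.elite > self.popsize:
            raise ValueError("elite cannot exceed popsize")
        if set(self.bounds) != set(FIT_PARAMETER_NAMES):
            raise ValueError(
                f"bounds must cover exactly {FIT_PARAMETER_NAMES}"
            )


@dataclass(frozen=True)
class GIFitResult:
    """Elite-set summary of a differential-evolution fit."""

    means: dict                  # parameter -> mean over elite
    standard_errors: dict        # parameter -> sd/sqrt(elite)
    k_In_UIn: float              # derived from the means (steady state)
    iPGl_end: float              # derived from the means (steady state)
    rss: float                   # objective at the best member
    rmspe_glucose_pct: float
    rmspe_insulin_pct: float
    best: dict                   # parameter -> best single member
    generations: int
    popsize: int
    elite: int
    seed: int | None
    best_per_generation: np.ndarray   # running best objective

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["best_per_generation"] = [float(v) for v in self.best_per_generation]
        return d


def candidate_params(
    x: np.ndarray, base: ModelParameters
) -> ModelParameters:
    """Materialize a candidate vector as a steady-state-consistent
    parameter set (k_In_UIn, iPGl_end and iIs re-derived)."""
    changes = dict(zip(FIT_PARAMETER_NAMES, (float(v) for v in x)))
    return apply_steady_state(base.replace(**changes))


def objective(
    x: np.ndarray,
    glucose: Timecourse,
    insulin: Timecourse,
    base: ModelParameters,
    z: ZSchedule,
    dt: float = 0.002,
    horizon: float = 420.0,
    report_every: float = 1.0,
) -> float:
    """Unweighted RSS of glucose plus insulin concentration residuals.

    Candidates whose simulation fails are culled with an infinite
    objective.
    """
    try:
        p = candidate_params(x, base)
        traj = simulate(p, z, horizon=horizon, dt=dt,
                        report_every=report_every)
    except (SimulationError, ValueError):
        return np.inf
    r_gl = traj.sample("glucose", glucose.times) - glucose.values
    r_in = traj.sample("insulin", insulin.times) - insulin.values
    with np.errstate(over="ignore"):  # wild candidates overflow to inf
        return float(np.sum(r_gl ** 2) + np.sum(r_in ** 2))


def fit(
    glucose: Timecourse,
    insulin: Timecourse,
    base: ModelParameters,
    z: ZSchedule,
    config: GIFitConfig | None = None,
) -> GIFitResult:
    """Run the evolutionary fit and summarize the elite set.

    ``base`` carries everything that is measured rather than fitted
    (BW, doses, iGl_P, iGl_S and the marker-derived k_SP2/k_SP3); ``z``
    is the marker-derived outflow schedule.
    """
    config = config or GIFitConfig()
    bounds = [tuple(config.bounds[name]) for name in FIT_PARAMETER_NAMES]

    best_history: list[float] = []

    def callback(intermediate_result):
        best_history.append(float(intermediate_result.fun))

    result = differential_evolution(
        objective,
        bounds,
        args=(glucose, insulin, base, z, config.dt, config.horizon,
              config.report_every),
        strategy=config.strategy,
        maxiter=config.generations,
        popsize=max(1, config.popsize // len(FIT_PARAMETER_NAMES)),
        mutation=config.mutation,
        recombination=config.recombination,
        seed=config.seed,
        tol=0.0,
        atol=0.0,
        polish=False,
        init="latinhypercube",
        updating="immediate",
        callback=callback,
    )

    population = result.population
    energies = result.population_energies
    order = np.argsort(energies, kind="stable")
    elite_idx = order[: config.elite]
    elite = population[elite_idx]

    means = {name: float(m) for name, m in
             zip(FIT_PARAMETER_NAMES, elite.mean(axis=0))}
    if len(elite) > 1:
        sd = elite.std(axis=0, ddof=1)
    else:
        sd = np.zeros(elite.shape[1])
    ses = {name: float(s / np.sqrt(len(elite))) for name, s in
           zip(FIT_PARAMETER_NAMES, sd)}

    mean_params = candidate_params(
        np.array([means[n] for n in FIT_PARAMETER_NAMES]), base
    )
    best_x = population[order[0]]
    best_params = candidate_params(best_x, base)
    traj = simulate(best_params, z, horizon=config.horizon, dt=config.dt,
                    report_every=config.report_every)
    rmspe_gl = rmspe(traj.sample("glucose", glucose.times), glucose.values)
    rmspe_in = rmspe(traj.sample("insulin", insulin.times), insulin.values)

    return GIFitResult(
        means=means,
        standard_errors=ses,
        k_In_UIn=mean_params.k_In_UIn,
        iPGl_end=mean_params.iPGl_end,
        rss=float(energies[order[0]]),
        rmspe_glucose_pct=rmspe_gl,
        rmspe_insulin_pct=rmspe_in,
        best={name: float(v) for name, v in zip(FIT_PARAMETER_NAMES, best_x)},
        generations=config.generations,
        popsize=len(population),
        elite=len(elite),
        seed=config.seed,
        best_per_generation=np.array(best_history),
    )
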