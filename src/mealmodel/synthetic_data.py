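"""Reference animal, meal-to-dose arithmetic, and synthetic observations.

Everything needed to exercise the fitting and sensitivity machinery
without external data: the built-in reference parameter set (a 60-kg
calf consuming a 2-L milk-replacer meal), conversion of meal descriptors
to initial stomach loads, and a seeded generator of noisy observed
timecourses that mimics the 12-sample postprandial protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gastric_fit import Timecourse
from .model_core import ModelParameters, ZSchedule
from .simulator import simulate

__all__ = [
    "MealSpec",
    "hexose_load",
    "ac_dose",
    "reference_animal",
    "reference_meal",
    "large_meal",
    "generate_observations",
    "OBSERVATION_TIMES",
]

LACTOSE_MOLAR_MASS = 342.3  # g/mol, anhydrous

#: post-meal sampling grid, min (the -30-min pre-meal draw remapped to 0)
OBSERVATION_TIMES = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0,
                     210.0, 240.0, 300.0, 360.0, 420.0)

#: reference gastric-outflow pattern: fast initial emptying followed by
#: intermittent slow gushes, one code per 30-min interval over 0-420 min
REFERENCE_Z_CODES = (2, 1, 2, 2, 1, 0, 0, 1, 1, 1, 0, 0, 0, 0)


@dataclass(frozen=True)
class MealSpec:
    """Liquid-meal descriptors from which stomach loads are computed."""

    volume: float                              # L
    dry_matter: float                          # g/L
    lactose_fraction: float                    # of dry matter
    galactose_to_glucose_fraction: float = 0.10
    glucose_splanchnic_survival: float = 0.90
    lactose_digestibility: float = 1.0

    def __post_init__(self) -> None:
        if self.volume < 0 or self.dry_matter < 0:
            raise ValueError("volume and dry_matter must be >= 0")
        for name in ("lactose_fraction", "galactose_to_glucose_fraction",
                     "glucose_splanchnic_survival", "lactose_digestibility"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def hexose_load(meal: MealSpec) -> float:
    """Meal hexose-equivalents reaching circulation as free glucose, mmol.

    Each mole of digested lactose yields one glucose moiety (of which
    ``glucose_splanchnic_survival`` survives splanchnic extraction) and
    one galactose moiety (of which ``galactose_to_glucose_fraction``
    appears as free glucose).
    """
    grams = meal.volume * meal.dry_matter * meal.lactose_fraction
    moles = grams * meal.lactose_digestibility / LACTOSE_MOLAR_MASS
    yield_per_mol = (meal.glucose_splanchnic_survival
                     + meal.galactose_to_glucose_fraction)
    return 1000.0 * moles * yield_per_mol


def ac_dose(bw: float, rate: float = 150.0) -> float:
    """Oral acetaminophen marker dose, mg (``rate`` mg per kg BW^0.75)."""
    if bw <= 0:
        raise ValueError(f"bw must be > 0, got {bw}")
    return rate * bw ** 0.75


def reference_meal() -> MealSpec:
    """The 2-L milk-replacer meal (150 g/L dry matter, 45.2% lactose)."""
    return MealSpec(volume=2.0, dry_matter=150.0, lactose_fraction=0.452)


def large_meal() -> MealSpec:
    """The 4-L variant of the same replacer (~double the hexose load)."""
    return MealSpec(volume=4.0, dry_matter=150.0, lactose_fraction=0.452)


def reference_animal() -> tuple[ModelParameters, ZSchedule]:
    """Built-in reference parameter set and its outflow schedule.

    A 60-kg calf given 3234 mg of marker and a 396-mmol hexose load,
    with the reference 14-interval schedule on a uniform 30-min grid.
    """
    params = ModelParameters(
        BW=60.0,
        iAc_S=3234.0,
        iAc_P=0.0,
        iGl_S=396.0,
        iGl_P=90.0,
        iIn_P=5.92,
        iIs=0.393,
        k_SP2=0.0015,
        k_SP3=0.003,
        k_Ac_UAc=0.0022,
        k_Gl_UGl=8.7e-7,
        k_Is_UGl=0.0757,
        iPGl_end=0.178,
        T_lag_SP=15.0,
        T_lag_IS=16.0,
        V_PIn=10.0,
        K_Gl_PIn=8.8,
        exp_PIn=9.0,
        k_In_UIn=0.7,
    )
    z = ZSchedule.uniform(REFERENCE_Z_CODES, spacing=30.0)
    return params, z


def generate_observations(
    params: ModelParameters,
    z: ZSchedule,
    sample_times=OBSERVATION_TIMES,
    noise_cv: float = 0.0,
    seed: int | None = None,
    dt: float = 0.002,
    report_every: float = 1.0,
) -> tuple[Timecourse, Timecourse, Timecourse]:
    """Simulate and sample noisy observed timecourses (Ac, Gl, In).

    Noise is multiplicative lognormal with unit mean and coefficient of
    variation ``noise_cv`` (concentrations are positive and assay errors
    scale with level); ``noise_cv=0`` returns exact model output.
    """
    if noise_cv < 0:
        raise ValueError(f"noise_cv must be >= 0, got {noise_cv}")
    sample_times = np.asarray(sample_times, dtype=float)
    horizon = float(sample_times[-1])
    traj = simulate(params, z, horizon=horizon, dt=dt,
                    report_every=report_every)
    rng = np.random.default_rng(seed)

    out = []
    for analyte in ("acetaminophen", "glucose", "insulin"):
        values = traj.sample(analyte, sample_times)
        if noise_cv > 0:
            sigma = np.sqrt(np.log1p(noise_cv ** 2))
            factors = np.exp(rng.normal(size=values.shape) * sigma
                             - 0.5 * sigma ** 2)
            values = values * factors
        out.append(Timecourse(sample_times, values, analyte=analyte))
    return tuple(out)
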