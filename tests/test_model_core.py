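import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mealmodel.model_core import (
    Fluxes,
    ModelParameters,
    ModelState,
    ParameterError,
    ZSchedule,
    ZScheduleError,
    apply_steady_state,
    concentrations,
    emptying_rate,
    fluxes,
    insulin_secretion,
    steady_state_iPGl_end,
    steady_state_k_In_UIn,
)


def basal_state(params):
    return ModelState(
        t=0.0, Ac_S=params.iAc_S, Ac_P=params.iAc_P,
        Gl_S=params.iGl_S, Gl_P=params.iGl_P, In_P=params.iIn_P,
    )


class TestParameters:
    def test_reference_values(self, ref_params):
        assert ref_params.k_SP2 == 0.0015
        assert ref_params.k_SP3 == 0.003
        assert ref_params.vd_Ac == 0.9
        assert ref_params.vd_GlIn == 0.251

    @pytest.mark.parametrize(
        "changes",
        [
            {"BW": 0.0},
            {"BW": -1.0},
            {"K_Gl_PIn": 0.0},
            {"exp_PIn": 0.5},
            {"k_SP2": -0.001},
            {"iGl_S": -1.0},
            {"k_SP2": 0.01, "k_SP3": 0.005},  # fast < slow
        ],
    )
    def test_invalid_rejected(self, ref_params, changes):
        with pytest.raises(ParameterError):
            ref_params.replace(**changes)

    def test_from_dict_rejects_unknown_key(self, ref_params):
        d = ref_params.to_dict()
        d["k_bogus"] = 1.0
        with pytest.raises(ParameterError, match="k_bogus"):
            ModelParameters.from_dict(d)

    def test_round_trip(self, ref_params):
        assert ModelParameters.from_dict(ref_params.to_dict()) == ref_params


class TestState:
    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            ModelState(t=0, Ac_S=-1, Ac_P=0, Gl_S=0, Gl_P=0, In_P=0)

    def test_initial(self, ref_params):
        s = ModelState.initial(ref_params)
        assert s.Ac_S == ref_params.iAc_S == 3234.0
        assert s.Gl_S == ref_params.iGl_S == 396.0


class TestZSchedule:
    def test_lookup_and_clamp(self):
        z = ZSchedule([0, 30, 60], [2, 1])
        assert z.code_at(0) == 2
        assert z.code_at(29.999) == 2
        assert z.code_at(30) == 1          # tie goes right
        assert z.code_at(1e6) == 1         # beyond last breakpoint

    def test_validation(self):
        with pytest.raises(ZScheduleError):
            ZSchedule([0, 30, 30], [1, 1])          # not strictly increasing
        with pytest.raises(ZScheduleError):
            ZSchedule([10, 30], [1])                # must start at 0
        with pytest.raises(ZScheduleError):
            ZSchedule([0, 30], [1, 1, 1])           # value count mismatch
        with pytest.raises(ZScheduleError, match="interval 1"):
            ZSchedule([0, 30, 60], [1, 5])          # bad code names interval

    def test_uniform(self):
        z = ZSchedule.uniform([2, 1, 0], spacing=30.0)
        assert z.breakpoints == (0.0, 30.0, 60.0, 90.0)
        assert z.values == (2, 1, 0)


class TestEmptyingRate:
    def test_zero_code(self, ref_params):
        assert emptying_rate(0, ref_params) == 0.0

    def test_slow_fast(self, ref_params):
        assert emptying_rate(1, ref_params) == 0.0015
        assert emptying_rate(2, ref_params) == 0.003

    def test_invalid_code(self, ref_params):
        with pytest.raises(ZScheduleError, match="3"):
            emptying_rate(3, ref_params)


class TestConcentrations:
    def test_zero_ac(self, ref_params):
        s = basal_state(ref_params)
        cAc, _, _ = concentrations(s, ref_params)
        assert cAc == 0.0

    def test_glucose(self, ref_params):
        # 90 mmol into 0.251 * 60 = 15.06 L
        _, cGl, _ = concentrations(basal_state(ref_params), ref_params)
        assert cGl == pytest.approx(90.0 / 15.06, rel=1e-12)
        assert cGl == pytest.approx(5.976, abs=5e-4)

    def test_insulin_matches_basal_signal(self, ref_params):
        _, _, cIn = concentrations(basal_state(ref_params), ref_params)
        assert cIn == pytest.approx(0.393, abs=1e-3)
        assert cIn == pytest.approx(ref_params.iIs, abs=1e-4)


class TestFluxes:
    def test_basal_insulin_secretion(self, ref_params):
        # closed-form oracle: V / (1 + (K / cGl)^n)
        c_gl = 90.0 / 15.06
        expected = 10.0 / (1.0 + (8.8 / c_gl) ** 9)
        fl = fluxes(basal_state(ref_params), 0, 0.0, ref_params.iIs, ref_params)
        assert fl.PIn == pytest.approx(expected, rel=1e-12)
        assert fl.PIn == pytest.approx(0.298, abs=2e-3)

    def test_basal_utilization_balances_production(self, ref_params):
        c_gl = 90.0 / 15.06
        expected = 8.7e-7 * c_gl + 0.0757 * 0.393 * c_gl
        fl = fluxes(basal_state(ref_params), 0, 0.0, ref_params.iIs, ref_params)
        assert fl.UGl == pytest.approx(expected, rel=1e-12)
        assert fl.UGl == pytest.approx(ref_params.iPGl_end, abs=1e-3)

    def test_no_outflow_freezes_stomach(self, ref_params):
        fl = fluxes(basal_state(ref_params), 0, 0.0, 0.393, ref_params)
        assert fl.dGlS == 0.0
        assert fl.dAcS == 0.0

    def test_pgl_end_is_zero_order(self, ref_params):
        s = ModelState(t=100, Ac_S=1, Ac_P=1, Gl_S=1, Gl_P=500, In_P=50)
        fl = fluxes(s, 2, 1.0, 2.0, ref_params)
        assert fl.PGl_end == ref_params.iPGl_end

    def test_stomach_masses_non_increasing(self, ref_params):
        for code in (0, 1, 2):
            fl = fluxes(basal_state(ref_params), code, 0.0, 0.393, ref_params)
            assert fl.dAcS <= 0.0
            assert fl.dGlS <= 0.0

    def test_nonnegative_when_state_nonneg(self, ref_params):
        s = ModelState(t=5, Ac_S=10, Ac_P=3, Gl_S=200, Gl_P=120, In_P=20)
        fl = fluxes(s, 2, 0.5, 1.2, ref_params)
        for name in ("PGl_ex", "UGl", "PIn", "UIn"):
            assert getattr(fl, name) >= 0.0

    def test_secretion_zero_glucose_limit(self, ref_params):
        assert insulin_secretion(0.0, ref_params) == 0.0
        assert insulin_secretion(1e-300, ref_params) == 0.0

    @given(
        c1=st.floats(0.01, 50.0),
        c2=st.floats(0.01, 50.0),
        n=st.floats(1.0, 20.0),
    )
    def test_secretion_monotone_and_bounded(self, c1, c2, n):
        params, _ = _reference()
        p = params.replace(exp_PIn=n)
        lo, hi = sorted((c1, c2))
        s_lo, s_hi = insulin_secretion(lo, p), insulin_secretion(hi, p)
        assert s_lo <= s_hi <= p.V_PIn


def _reference():
    from mealmodel import reference_animal

    return reference_animal()


class TestSteadyState:
    def test_k_in_uin_value(self, ref_params):
        c_in = 5.92 / 15.06
        c_gl = 90.0 / 15.06
        expected = 10.0 / c_in / (1.0 + (8.8 / c_gl) ** 9)
        got = steady_state_k_In_UIn(ref_params)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.758, abs=1e-3)

    def test_k_in_uin_linear_in_vpin(self, ref_params):
        base = steady_state_k_In_UIn(ref_params)
        doubled = steady_state_k_In_UIn(ref_params.replace(V_PIn=20.0))
        assert doubled == pytest.approx(2.0 * base, rel=1e-12)

    def test_k_in_uin_small_k_limit(self, ref_params):
        got = steady_state_k_In_UIn(ref_params.replace(K_Gl_PIn=1e-9))
        assert got == pytest.approx(
            ref_params.V_PIn / ref_params.basal_cIn_P, rel=1e-9
        )

    def test_k_in_uin_requires_basal_insulin(self, ref_params):
        with pytest.raises(ParameterError):
            steady_state_k_In_UIn(ref_params.replace(iIn_P=0.0))

    def test_ipgl_end_reference(self, ref_params):
        got = steady_state_iPGl_end(ref_params)
        assert got == pytest.approx(0.17784, abs=5e-6)
        assert round(got, 3) == 0.178

    def test_ipgl_end_zero_without_disposal(self, ref_params):
        p = ref_params.replace(k_Gl_UGl=0.0, k_Is_UGl=0.0)
        assert steady_state_iPGl_end(p) == 0.0

    def test_ipgl_end_linear_in_basal_glucose(self, ref_params):
        base = steady_state_iPGl_end(ref_params)
        doubled = steady_state_iPGl_end(ref_params.replace(iGl_P=180.0))
        assert doubled == pytest.approx(2.0 * base, rel=1e-12)

    def test_apply_steady_state_balances_fluxes(self, ref_params):
        p = apply_steady_state(ref_params)
        fl = fluxes(basal_state(p), 0, 0.0, p.iIs, p)
        assert fl.PIn - fl.UIn == pytest.approx(0.0, abs=1e-14)
        assert fl.PGl_ex + fl.PGl_end - fl.UGl == pytest.approx(0.0, abs=1e-14)


# ---------------------------------------------------------------------------
# dimensional consistency: re-derive every flux expression with unit algebra
# ---------------------------------------------------------------------------

class Q:
    """Minimal quantity-with-dimensions for unit bookkeeping."""

    def __init__(self, value, **dims):
        self.value = value
        self.dims = {k: v for k, v in dims.items() if v != 0}

    def _combine(self, other, sign):
        dims = dict(self.dims)
        for k, v in other.dims.items():
            dims[k] = dims.get(k, 0) + sign * v
            if dims[k] == 0:
                del dims[k]
        return dims

    def __mul__(self, other):
        return Q(self.value * other.value, **self._combine(other, +1))

    def __truediv__(self, other):
        return Q(self.value / other.value, **self._combine(other, -1))

    def __add__(self, other):
        assert self.dims == other.dims, f"{self.dims} + {other.dims}"
        return Q(self.value + other.value, **self.dims)

    def __pow__(self, n):
        assert not self.dims, "exponent base must be dimensionless"
        return Q(self.value ** n)


def test_flux_dimensions(ref_params):
    p = ref_params
    per_min = {"min": -1}
    mg, mmol, ug, L, mins = (
        Q(1, mg=1), Q(1, mmol=1), Q(1, ug=1), Q(1, L=1), Q(1, min=1)
    )

    ac_s = Q(p.iAc_S, mg=1)
    gl_p = Q(p.iGl_P, mmol=1)
    in_p = Q(p.iIn_P, ug=1)
    vol = Q(p.v_plasma_glin, L=1)
    c_gl = gl_p / vol                                  # mmol/L
    c_in = in_p / vol                                  # ug/L
    k_sp = Q(p.k_SP3, min=-1)
    k_gl = Q(p.k_Gl_UGl, L=1, min=-1)
    k_is = Q(p.k_Is_UGl, L=2, ug=-1, min=-1)
    k_in = Q(p.k_In_UIn, L=1, min=-1)

    d_ac_s = k_sp * ac_s
    assert d_ac_s.dims == {"mg": 1, "min": -1}

    u_gl = k_gl * c_gl + k_is * c_in * c_gl
    assert u_gl.dims == {"mmol": 1, "min": -1}

    hill = (Q(p.K_Gl_PIn, mmol=1, L=-1) / c_gl) ** p.exp_PIn
    p_in = Q(p.V_PIn, ug=1, min=-1) / (Q(1) + hill)
    assert p_in.dims == {"ug": 1, "min": -1}

    u_in = k_in * c_in
    assert u_in.dims == {"ug": 1, "min": -1}

    pgl_ex = k_sp * Q(p.iGl_S, mmol=1)
    assert pgl_ex.dims == {"mmol": 1, "min": -1}
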