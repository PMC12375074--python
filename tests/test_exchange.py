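"""Forward-model unit and property tests for the exchange simulators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from loopex import (ExchangeModel, CESTSchedule, CPMGSchedule, EXSYSchedule,
                    IRSchedule, SpectrumGrid, simulate_ir_single,
                    simulate_ir_two_state, simulate_cest, simulate_cpmg,
                    simulate_cpmg_numeric, simulate_exsy, simulate_lineshape)
from loopex.exchange import cest_evolution_matrix, _CEST_PROJ
from scipy.linalg import expm


# ---------------------------------------------------------------------------
# inversion recovery
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("R1, I_inf, t, expected", [
    (1.0, 1.0, 0.0, -1.0),                       # inversion at zero delay
    (1.0, 1.0, np.log(2.0), 0.0),                # analytic null point
    (0.5, 2.0, 2.0, 2.0 * (1 - 2 * np.exp(-1))),  # hand evaluation
])
def test_ir_single_known_values(R1, I_inf, t, expected):
    out = simulate_ir_single(R1, IRSchedule(delays=np.array([t, 1.0, 9.0]),
                                            I_inf=I_inf))
    assert out[0] == pytest.approx(expected, abs=1e-12)


def test_ir_single_rejects_negative_rate():
    with pytest.raises(ValueError, match="R1"):
        simulate_ir_single(-0.1, IRSchedule(delays=np.array([0.1, 1, 2])))


def test_ir_single_monotone_recovery():
    sched = IRSchedule(delays=np.linspace(0, 8, 40), I_inf=1.0)
    out = simulate_ir_single(0.7, sched)
    assert np.all(np.diff(out) > 0)


def test_ir_two_state_starts_inverted(slow_model):
    sched = IRSchedule(delays=np.array([0.0, 1.0, 50.0]), I_inf=2.0)
    out = simulate_ir_two_state(slow_model, sched)
    assert out[0] == pytest.approx(-2.0, abs=1e-10)     # -(p_G+p_E) * I_inf
    assert out[-1] == pytest.approx(2.0, rel=1e-6)      # full recovery


def test_ir_two_state_decoupled_limit():
    model = ExchangeModel(p_E=0.3, k_ex=0.0, R1_G=0.9, R1_E=0.9)
    sched = IRSchedule(delays=np.linspace(0, 6, 12))
    np.testing.assert_allclose(simulate_ir_two_state(model, sched),
                               simulate_ir_single(0.9, sched), atol=1e-12)


def test_ir_two_state_matches_ode_oracle():
    """Slow-exchange PRE recovery against fine-step ODE integration."""
    model = ExchangeModel(p_E=0.26, k_ex=35.0, R1_G=0.8, R1_E=1.2,
                          Gamma1_E=5.0)
    delays = np.array([0.001, 0.05, 0.1, 0.25, 0.5, 0.8, 1.5, 3, 5])
    sched = IRSchedule(delays=delays)
    ref = oracles.ir_two_state_ode(0.26, 35.0, 0.8, 1.2, 0.0, 5.0, delays)
    calc = simulate_ir_two_state(model, sched)
    assert oracles.amplitude_relative_error(calc, ref) < 1e-8


# ---------------------------------------------------------------------------
# CEST
# ---------------------------------------------------------------------------

def _cest_sched(B1, offsets):
    return CESTSchedule(B1=B1, t_CEST=0.4, offsets=np.asarray(offsets, float))


def test_cest_no_saturation_is_flat(slow_model):
    prof = simulate_cest(slow_model, _cest_sched(0.0, np.linspace(-2450, 2450, 15)))
    np.testing.assert_allclose(prof, 1.0, atol=1e-12)


def test_cest_single_state_profile_is_symmetric():
    model = ExchangeModel(p_E=0.0, k_ex=500.0, omega_G=0.0, omega_E=940.0,
                          R1_G=1.0, R1_E=1.0, R2_G=80.0, R2_E=80.0)
    delta = np.array([50.0, 150.0, 400.0, 900.0])
    plus = simulate_cest(model, _cest_sched(25.0, model.omega_G + delta))
    minus = simulate_cest(model, _cest_sched(25.0, model.omega_G - delta))
    np.testing.assert_allclose(plus, minus, atol=1e-10)


def test_cest_minor_dip_at_excited_shift(slow_model):
    """The spec'd slow-exchange case: a minor dip appears at omega_E."""
    offsets = np.linspace(-2450, 2450, 67)
    prof = simulate_cest(slow_model, _cest_sched(25.0, offsets))
    ref = oracles.cest_ode(0.26, 35.0, 0.0, 940.0, offsets, [-1e4, 1e4],
                           25.0, 0.4, 0.8, 0.8, 120.0, 120.0)
    assert np.max(np.abs(prof - ref) / np.abs(ref)) < 1e-6
    near_e = np.abs(offsets - 940.0) < 80
    mirrored = np.abs(offsets + 940.0) < 80
    assert prof[near_e].min() < prof[mirrored].min() - 0.05


def test_cest_profile_bounded(slow_model, fast_model):
    offsets = np.linspace(-2450, 2450, 67)
    for m in (slow_model, fast_model):
        prof = simulate_cest(m, _cest_sched(25.0, offsets))
        assert np.all(prof > 0) and np.all(prof <= 1.02)


def test_cest_dip_area_grows_with_saturation_field(slow_model):
    offsets = np.linspace(-2450, 2450, 67)
    areas = [np.sum(1.0 - simulate_cest(slow_model, _cest_sched(b1, offsets)))
             for b1 in (10.0, 15.0, 25.0)]
    assert areas[0] < areas[1] < areas[2]


def test_cest_eig_propagation_matches_expm(slow_model):
    """Internal stacked-eigendecomposition path equals scaling-and-squaring."""
    offsets = np.linspace(-2450, 2450, 15)
    sched = _cest_sched(25.0, offsets)
    prof = simulate_cest(slow_model, sched)
    v0 = np.array([0.5, 0, 0, slow_model.p_G, 0, 0, slow_model.p_E])

    def by_expm(off):
        M = cest_evolution_matrix(slow_model, off, 25.0)
        return _CEST_PROJ @ (expm(M * 0.4) @ v0)

    raw = np.array([by_expm(o) for o in offsets])
    ref = np.mean([by_expm(o) for o in (-1e4, 1e4)])
    np.testing.assert_allclose(prof, raw / ref, rtol=1e-10)


def test_cest_fails_on_saturating_reference():
    model = ExchangeModel(p_E=0.26, k_ex=35.0, omega_E=940.0,
                          R1_G=0.0, R1_E=0.0, R2_G=120.0, R2_E=120.0)
    sched = CESTSchedule(B1=2500.0, t_CEST=30.0,
                         offsets=np.array([0.0]),
                         reference_offsets=np.array([-10.0, 10.0]))
    with pytest.raises(ZeroDivisionError):
        simulate_cest(model, sched)


# ---------------------------------------------------------------------------
# CPMG
# ---------------------------------------------------------------------------

def _cpmg_sched(T=0.01, nu=None, freq=471.0):
    if nu is None:
        nu = np.arange(1, 51, 2) * 100.0
    return CPMGSchedule(T_CPMG=T, nu_CPMG=np.asarray(nu, float),
                        spectrometer_freq=freq)


def test_cpmg_no_exchange_is_flat():
    model = ExchangeModel(p_E=0.0, k_ex=900.0, omega_E=940.0, R2_G=85.0,
                          R2_E=85.0)
    out = simulate_cpmg(model, _cpmg_sched())
    np.testing.assert_allclose(out, 85.0, atol=1e-10)
    np.testing.assert_allclose(simulate_cpmg_numeric(model, _cpmg_sched()),
                               85.0, atol=1e-10)


def test_cpmg_zero_shift_difference_is_flat():
    model = ExchangeModel(p_E=0.2, k_ex=800.0, omega_G=300.0, omega_E=300.0,
                          R2_G=60.0, R2_E=60.0)
    np.testing.assert_allclose(simulate_cpmg(model, _cpmg_sched()), 60.0,
                               atol=1e-10)


def test_cpmg_closed_form_matches_pulse_train(fast_model):
    sched = _cpmg_sched(nu=np.arange(1, 21) * 100.0)
    a = simulate_cpmg(fast_model, sched)
    b = simulate_cpmg_numeric(fast_model, sched)
    assert np.max(np.abs(a - b) / b) < 5e-3


def test_cpmg_dispersion_decreases(fast_model, slow_model):
    """Exchange is progressively refocused: the dispersion relaxes from its
    low-frequency level to the intrinsic rate.  The exact solution ripples
    slightly when only one or two echo cycles fit into T_CPMG, so strict
    monotonicity is asserted in the many-cycle regime plus the end-to-end
    inequality R2eff(nu_max) <= R2eff(nu_min)."""
    for m in (fast_model, slow_model):
        sched = _cpmg_sched()
        out = simulate_cpmg(m, sched)
        assert out[-1] <= out[0]
        many = sched.nu_CPMG >= 500.0
        assert np.all(np.diff(out[many]) <= 1e-8)


def test_cpmg_fast_exchange_limit():
    """k_ex >> dw: dispersion follows the analytic fast-exchange form."""
    dw = 2 * np.pi * 940.0
    p_E, kex, R2 = 0.1, 2e5, 50.0
    model = ExchangeModel(p_E=p_E, k_ex=kex, omega_E=940.0, R2_G=R2, R2_E=R2)
    sched = _cpmg_sched()
    out = simulate_cpmg(model, sched)
    nu = sched.nu_CPMG
    rex = (1 - p_E) * p_E * dw ** 2 / kex \
        * (1 - 4 * nu / kex * np.tanh(kex / (4 * nu)))
    np.testing.assert_allclose(out, R2 + rex, rtol=1e-2)


def test_cpmg_rejects_zero_frequency():
    with pytest.raises(ValueError):
        CPMGSchedule(T_CPMG=0.01, nu_CPMG=np.array([0.0, 100.0]))


def test_cpmg_off_grid_frequency_rounded():
    with pytest.warns(UserWarning, match="integer number"):
        s = CPMGSchedule(T_CPMG=0.01, nu_CPMG=np.array([130.0]))
    assert s.nu_CPMG[0] == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# EXSY
# ---------------------------------------------------------------------------

def test_exsy_zero_mixing_is_diagonal(slow_model):
    sched = EXSYSchedule(mixing_times=np.array([0.0, 0.1]), scale=3.0)
    out = simulate_exsy(slow_model, sched)
    np.testing.assert_allclose(
        out[0], 3.0 * np.diag([slow_model.p_G, slow_model.p_E]), atol=1e-14)


def test_exsy_cross_peaks_equal_for_shared_R1(slow_model):
    sched = EXSYSchedule(mixing_times=np.array([0.01, 0.05, 0.2, 0.6]))
    out = simulate_exsy(slow_model, sched)
    np.testing.assert_allclose(out[:, 0, 1], out[:, 1, 0], rtol=1e-12)


def test_exsy_long_time_equilibrium_products():
    """R1=0, t->inf: intensities factorize into population products."""
    model = ExchangeModel(p_E=0.26, k_ex=35.0, R1_G=0.0, R1_E=0.0)
    out = simulate_exsy(model, EXSYSchedule(mixing_times=np.array([5.0])))[0]
    pg, pe = model.p_G, model.p_E
    np.testing.assert_allclose(out, [[pg * pg, pg * pe], [pe * pg, pe * pe]],
                               atol=1e-6)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(p_E=st.floats(0.01, 0.5), k_ex=st.floats(0.1, 500.0),
       t=st.floats(0.0, 2.0))
def test_exsy_conserves_z_magnetization_without_relaxation(p_E, k_ex, t):
    model = ExchangeModel(p_E=p_E, k_ex=k_ex, R1_G=0.0, R1_E=0.0)
    times = np.array([t]) if t > 0 else np.array([0.0])
    out = simulate_exsy(model, EXSYSchedule(mixing_times=times))
    assert out[0].sum() == pytest.approx(1.0, abs=1e-10)
    assert np.all(out >= -1e-12)


# ---------------------------------------------------------------------------
# lineshape
# ---------------------------------------------------------------------------

def test_lineshape_decoupled_is_two_lorentzians():
    model = ExchangeModel(p_E=0.3, k_ex=0.0, omega_G=-400.0, omega_E=600.0,
                          R2_G=100.0, R2_E=150.0)
    grid = SpectrumGrid(offsets=np.linspace(-2000, 2000, 4001))
    spec = simulate_lineshape(model, grid)
    w = 2 * np.pi * grid.offsets
    lor = (model.p_G * model.R2_G
           / (model.R2_G ** 2 + (2 * np.pi * model.omega_G - w) ** 2)
           + model.p_E * model.R2_E
           / (model.R2_E ** 2 + (2 * np.pi * model.omega_E - w) ** 2))
    np.testing.assert_allclose(spec, lor, rtol=1e-10)
    # half-width at half height of the isolated ground peak is R2/(2pi) Hz
    fine = SpectrumGrid(offsets=np.linspace(-500, -300, 4001))
    spec_g = simulate_lineshape(model, fine)
    peak = spec_g.max()
    above = fine.offsets[spec_g >= peak / 2]
    hwhh = (above.max() - above.min()) / 2
    assert hwhh == pytest.approx(model.R2_G / (2 * np.pi), rel=0.01)


def test_lineshape_fast_exchange_coalesces_at_average_shift():
    model = ExchangeModel(p_E=0.3, k_ex=8e5, omega_G=0.0, omega_E=940.0,
                          R2_G=40.0, R2_E=40.0)
    grid = SpectrumGrid(offsets=np.linspace(-500, 1500, 8001))
    spec = simulate_lineshape(model, grid)
    peak = grid.offsets[np.argmax(spec)]
    avg = model.p_G * model.omega_G + model.p_E * model.omega_E
    assert peak == pytest.approx(avg, abs=2.0)


def test_lineshape_pre_broadening_attenuates_excited_peak(slow_model):
    """Transverse PRE attenuates the excited-state peak core (intensity is
    redistributed to the wings, so the comparison is within the peak's
    original half-width around omega_E)."""
    slow_model.Gamma2_E = 200.0
    grid = SpectrumGrid(offsets=np.linspace(915, 965, 101))
    dia = simulate_lineshape(slow_model, grid, use_pre=False)
    para = simulate_lineshape(slow_model, grid, use_pre=True)
    assert np.all(para < dia)


def test_lineshape_matches_dense_inverse(slow_model):
    grid = SpectrumGrid(offsets=np.linspace(-2450, 2450, 201), scale=2.5)
    ref = oracles.lineshape_solve(0.26, 35.0, 0.0, 940.0, 120.0, 120.0,
                                  0.0, 0.0, grid.offsets, scale=2.5)
    np.testing.assert_allclose(simulate_lineshape(slow_model, grid), ref,
                               rtol=1e-10)


# ---------------------------------------------------------------------------
# model invariants
# ---------------------------------------------------------------------------

@settings(deadline=None, max_examples=50, derandomize=True)
@given(p_E=st.floats(0.0, 1.0), k_ex=st.floats(0.0, 1e6))
def test_exchange_model_detailed_balance(p_E, k_ex):
    m = ExchangeModel(p_E=p_E, k_ex=k_ex)
    assert m.k_GE + m.k_EG == pytest.approx(k_ex, rel=1e-15, abs=1e-300)
    assert m.p_G * m.k_GE == pytest.approx(m.p_E * m.k_EG, rel=1e-12,
                                           abs=1e-300)


@pytest.mark.parametrize("bad", [
    dict(p_E=-0.1, k_ex=10.0), dict(p_E=1.2, k_ex=10.0),
    dict(p_E=0.2, k_ex=-5.0), dict(p_E=0.2, k_ex=5.0, R2_G=-1.0),
])
def test_exchange_model_rejects_invalid(bad):
    with pytest.raises(ValueError):
        ExchangeModel(**bad)


def test_static_two_species_allowed():
    """k_ex=0 with p_E>0 (two non-interconverting species) is legal."""
    m = ExchangeModel(p_E=0.25, k_ex=0.0, omega_E=300.0)
    grid = SpectrumGrid(offsets=np.linspace(-500, 800, 101))
    assert np.all(np.isfinite(simulate_lineshape(m, grid)))
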