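"""Model-core checks: rates, conservation, equilibria, perturbation wiring."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm, null_space

from epicard.model import (G_CAL, E_CAL, IDX, INITIAL_STATE, NA_MARKOV_STATES,
                           ModelState, derivatives, ical_activation_rates,
                           initial_state, na_markov_rates, na_rate_matrix,
                           pack_params, rhs)
from epicard.params import ModelParameters
from epicard.simulate import integrate_beats, resting_state


BASE = ModelParameters()


def test_published_initial_state_is_equilibrium():
    """The quiescent initial conditions are a fixed point of the RHS."""
    d = derivatives(initial_state(), BASE, i_stim=0.0)
    assert abs(d["V"]) < 1e-3


def test_resting_state_matches_tight_tolerance_integration():
    """Resting V from the production solver equals an independent stiff
    integration at rtol 1e-10 within 0.1 mV."""
    y_prod = resting_state(BASE, duration_s=2.0)
    sol = solve_ivp(rhs, (0.0, 2000.0), initial_state(),
                    args=(pack_params(BASE, 0.0),), method="BDF",
                    rtol=1e-10, atol=1e-12, dense_output=False)
    assert sol.success
    assert abs(y_prod[IDX["V"]] - sol.y[0, -1]) < 0.1


def test_na_markov_derivatives_conserve_probability():
    """The 9 Na_v occupancy derivatives sum to zero at arbitrary states."""
    rng = np.random.default_rng(0)
    for _ in range(20):
        y = initial_state()
        y[IDX["V"]] = rng.uniform(-100, 40)
        occ = rng.dirichlet(np.ones(9))
        y[IDX["C_Na2"]:IDX["IC_Na3"] + 1] = occ[1:]
        d = derivatives(y, BASE)
        total = d["C_Na3"] + sum(d[s] for s in NA_MARKOV_STATES[1:])
        assert abs(total) < 1e-14


def test_rhs_na_block_consistent_with_labelled_rates():
    """The compiled RHS and the labelled rate matrix agree on dp/dt."""
    rng = np.random.default_rng(1)
    for V in (-80.0, -40.0, 0.0, 30.0):
        for k in (1.0, 1.5):
            y = initial_state()
            y[IDX["V"]] = V
            occ = rng.dirichlet(np.ones(9))
            y[IDX["C_Na2"]:IDX["IC_Na3"] + 1] = occ[1:]
            d = derivatives(y, BASE.with_k_reopen(k))
            Q = na_rate_matrix(V, k)
            dp = Q @ occ
            got = np.array([d["C_Na3"]] + [d[s] for s in NA_MARKOV_STATES[1:]])
            np.testing.assert_allclose(got, dp, rtol=1e-10, atol=1e-12)


def test_na_markov_rates_identity_and_selective_scaling():
    base = na_markov_rates(-80.0, 1.0)
    scaled = na_markov_rates(-80.0, 1.5)
    assert scaled["IF_Na->O_Na"] == pytest.approx(1.5 * base["IF_Na->O_Na"])
    for edge in base:
        if edge != "IF_Na->O_Na":
            assert scaled[edge] == base[edge]
    assert all(r >= 0 for r in base.values())


def test_na_markov_rates_input_validation():
    with pytest.raises(ValueError):
        na_markov_rates(np.nan, 1.0)
    with pytest.raises(ValueError):
        na_markov_rates(-80.0, 0.0)


@pytest.mark.parametrize("V,k", [(-50.0, 1.0), (-20.0, 1.5)])
def test_clamped_markov_relaxes_to_null_space(V, k):
    """Long clamped integration of the isolated Na_v block reaches the
    stationary distribution given by the rate-matrix null space."""
    Q = na_rate_matrix(V, k)
    p0 = np.zeros(9)
    p0[0] = 1.0
    p_t = expm(Q * 1e9) @ p0   # far beyond the slowest relaxation mode
    ns = null_space(Q)
    assert ns.shape[1] == 1
    p_inf = ns[:, 0] / ns[:, 0].sum()
    np.testing.assert_allclose(p_t, p_inf, atol=1e-6)


def test_ical_activation_shift_moves_rates_not_identity():
    a0, b0 = ical_activation_rates(-10.0, 0.0)
    a_s, b_s = ical_activation_rates(-10.0, -15.0)
    a_ref, b_ref = ical_activation_rates(5.0, 0.0)
    assert a_s == pytest.approx(a_ref) and b_s == pytest.approx(b_ref)
    assert (a0, b0) != (a_s, b_s)


def _clamp_peak_ical(dv: float, V_steps: np.ndarray) -> float:
    """Voltage-clamp protocol: peak-current voltage of the I-V curve."""
    params = BASE.with_caL_shift(dv)
    p = pack_params(params, 0.0)
    y_rest = initial_state()

    def clamped_rhs(t, y, V):
        y = y.copy()
        y[IDX["V"]] = V
        d = rhs(t, y, p)
        d[IDX["V"]] = 0.0
        d[IDX["Nai"]] = d[IDX["Ki"]] = 0.0
        return d

    peaks = []
    for V in V_steps:
        y0 = y_rest.copy()
        y0[IDX["V"]] = V
        sol = solve_ivp(clamped_rhs, (0.0, 40.0), y0, args=(V,),
                        method="LSODA", rtol=1e-8, atol=1e-10,
                        t_eval=np.linspace(0, 40, 801))
        i_cal = G_CAL * sol.y[IDX["O_CaL"]] * (V - E_CAL)
        peaks.append(i_cal.min())
    return float(V_steps[int(np.argmin(peaks))])


def test_voltage_clamp_iv_peak_shifts_with_activation():
    """A -10 mV activation shift moves the I_CaL I-V peak about 10 mV
    more negative (voltage-clamp simulation oracle)."""
    steps = np.arange(-40.0, 21.0, 2.5)
    v_base = _clamp_peak_ical(0.0, steps)
    v_shift = _clamp_peak_ical(-10.0, steps)
    assert v_shift < v_base
    assert abs((v_base - v_shift) - 10.0) <= 2.0 + 1e-9


def test_derivatives_flags_non_finite_state():
    y = initial_state()
    y[IDX["Cai"]] = np.nan
    with pytest.raises(ValueError, match="Cai"):
        derivatives(y, BASE)


def test_markov_occupancies_stay_normalized_over_paced_run():
    """Probability conservation and bounds over a full paced simulation."""
    t, Y = integrate_beats(BASE, 5)
    na_sum = Y[:, IDX["C_Na2"]:IDX["IC_Na3"] + 1].sum(axis=1)
    c_na3 = 1.0 - na_sum
    assert np.all(c_na3 >= -1e-8) and np.all(na_sum <= 1 + 1e-8)
    occ = Y[:, IDX["C_Na2"]:IDX["IC_Na3"] + 1]
    assert occ.min() > -1e-7
    state = ModelState(Y[-1])
    state.validate()


def test_only_ik1_scaling_changes_resting_potential():
    """Among the scanned K+ currents, only I_K1 sets the resting V_m."""
    v_base = resting_state(BASE, duration_s=3.0)[IDX["V"]]
    v_k1 = resting_state(BASE.with_scale("K1", 0.5),
                         duration_s=3.0)[IDX["V"]]
    assert abs(v_k1 - v_base) > 0.5
    for cid in ("Ktof", "Kur", "Kss"):
        v = resting_state(BASE.with_scale(cid, 0.5),
                          duration_s=3.0)[IDX["V"]]
        assert abs(v - v_base) < 0.5


def test_model_state_accessors_and_validation():
    s = ModelState(initial_state())
    assert s.na_markov.shape == (9,)
    assert abs(s.na_markov.sum() - 1.0) < 1e-8
    assert np.all((s.hh_gates >= 0) & (s.hh_gates <= 1))
    assert all(v > 0 for v in s.concentrations.values())
    bad = initial_state()
    bad[IDX["Nai"]] = -1.0
    with pytest.raises(ValueError, match="Nai"):
        ModelState(bad).validate()
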