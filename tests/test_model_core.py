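import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dcvax
from dcvax.model import (
    DC_NAMES,
    STATE_NAMES,
    DCSignalingState,
    ModelState,
    OrganState,
    Scenario,
    TCellState,
    rest_signaling_state,
    rhs_biodistribution,
    rhs_dc_signaling,
    rhs_tcell,
    stimulation_signal,
)
from dcvax.parameters import DesignConstants, ParameterValidationError


def test_state_vector_has_exactly_25_components(ref_params):
    assert len(STATE_NAMES) == 25
    assert len(DC_NAMES) == 17
    state = ModelState.from_array(np.arange(25.0))
    assert state.as_array().shape == (25,)
    with pytest.raises(ValueError):
        ModelState.from_array(np.zeros(24))


# ---------------------------------------------------------------------------
# bio-distribution rate law
# ---------------------------------------------------------------------------

def test_spleen_balance_point(ref_params):
    """Influx mu_BS*(Q_B/Q_S)*DC_B exactly offsets efflux mu_S0*DC_S."""
    p = ref_params.with_overrides({"mu_BS": 0.02, "mu_S0": 0.01})
    p = p.with_overrides({})  # volumes are fixed; use explicit organ state
    organ = OrganState(dc_blood=100.0, dc_lung=0.0, dc_liver=0.0,
                      dc_spleen=0.02 * (p["Q_Blood"] / p["Q_Spleen"]) * 100.0 / 0.01)
    d = rhs_biodistribution(organ, p)
    assert d.dc_spleen == pytest.approx(0.0, abs=1e-9)


def test_spleen_decays_exponentially_without_blood_supply(ref_params):
    from scipy.integrate import solve_ivp

    from dcvax.model import _rhs_organ

    pvec = ref_params.as_array()
    y0 = np.array([0.0, 0.0, 0.0, 10.0])
    sol = solve_ivp(lambda t, y: _rhs_organ(y, pvec), (0, 50), y0,
                    rtol=1e-10, atol=1e-14, t_eval=[10.0, 50.0])
    expected = 10.0 * np.exp(-ref_params["mu_S0"] * np.array([10.0, 50.0]))
    np.testing.assert_allclose(sol.y[3], expected, rtol=1e-6)


def test_mass_balance_against_explicit_euler(ref_params):
    """Organ inventory plus integrated losses equals the injected amount.

    Oracle: fine-step explicit Euler integration of the organ block.
    """
    p = ref_params
    q = np.array([p["Q_Blood"], p["Q_Lung"], p["Q_Liver"], p["Q_Spleen"]])
    y = np.array([1e5 / p["Q_Blood"], 0.0, 0.0, 0.0])
    from dcvax.model import _rhs_organ

    pvec = p.as_array()
    dt, lost = 0.002, 0.0
    for _ in range(int(72 / dt)):
        loss_rate = (p["mu"] * q[0] * y[0] + p["mu_Lu0"] * q[1] * y[1]
                     + p["mu_S0"] * q[3] * y[3])
        lost += loss_rate * dt
        y = y + dt * _rhs_organ(y, pvec)
    total = float(q[0] * y[0] + q[1] * y[1] + q[2] * y[2] + q[3] * y[3])
    assert total + lost == pytest.approx(1e5, rel=1e-3)


def test_liver_is_terminal_reservoir(ref_trajectory):
    liver = ref_trajectory["dc_liver"]
    assert np.all(np.diff(liver) >= -1e-12 * liver.max())


# ---------------------------------------------------------------------------
# DC signaling rate law
# ---------------------------------------------------------------------------

def test_il8_basal_transcription_only(ref_params):
    dc = rest_signaling_state(ref_params)
    dc.nfkb, dc.m_il8 = 0.0, 0.0
    d = rhs_dc_signaling(dc, 0.0, ref_params)
    assert d.m_il8 == pytest.approx(ref_params["k_transc1_mIL8"])


def test_il8_transcription_hand_value(ref_params):
    """d(mIL8)/dt = k1 + k2*NFkB - kdeg*mIL8 = 1 + 1 - 0.5 = 1.5."""
    p = ref_params.with_overrides({"k_transc1_mIL8": 1.0,
                                   "k_transc2_mIL8": 2.0,
                                   "k_deg_mIL8": 0.1})
    dc = rest_signaling_state(p)
    dc.nfkb, dc.m_il8 = 0.5, 5.0
    d = rhs_dc_signaling(dc, 0.0, p)
    assert d.m_il8 == pytest.approx(1.5)


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(0.01, 2.0), min_size=17, max_size=17),
       st.floats(0.0, 1.0))
def test_moiety_derivative_identities(ref_params, state_vals, u):
    """Free NF-kB' + complex' = 0 and TRAF2' + TRAF2p' = 0 for any state."""
    dc = DCSignalingState(*state_vals)
    d = rhs_dc_signaling(dc, u, ref_params)
    scale = max(abs(d.nfkb), abs(d.nfkb_ikba), 1.0)
    assert d.nfkb + d.nfkb_ikba == pytest.approx(0.0, abs=1e-12 * scale)
    assert d.traf2 + d.traf2p == pytest.approx(0.0, abs=1e-12)
    assert d.irak1 + d.irak1p == pytest.approx(0.0, abs=1e-12)


def test_stimulus_bounds_enforced(ref_params):
    dc = rest_signaling_state(ref_params)
    with pytest.raises(ValueError):
        rhs_dc_signaling(dc, 1.5, ref_params)


# ---------------------------------------------------------------------------
# stimulation signal
# ---------------------------------------------------------------------------

def test_stimulation_signal_zero_without_spleen_dcs(ref_params):
    state = ModelState.from_array(np.ones(25))
    state.organ.dc_spleen = 0.0
    assert stimulation_signal(state, ref_params) == 0.0


def test_stimulation_signal_hand_value(ref_params):
    """S = (Q_S * DC_S) * (IL6 + IL8 + IL12) * CD70 = 100 * 0.75 * 0.25."""
    y = np.zeros(25)
    state = ModelState.from_array(y)
    state.organ.dc_spleen = 1e-3
    state.dc.il6 = state.dc.il8 = state.dc.il12 = state.dc.cd70 = 0.25
    s = stimulation_signal(state, ref_params)
    assert ref_params["Q_Spleen"] == 1e5
    assert s == pytest.approx(100.0 * 0.75 * 0.25)


def test_stimulation_signal_bilinear_scaling(ref_params):
    """Doubling the soluble cytokines doubles S; doubling CD70 as well
    quadruples it (soluble signal x contact costimulation)."""
    y = np.zeros(25)
    st_ = ModelState.from_array(y)
    st_.organ.dc_spleen = 1e-3
    st_.dc.il6 = st_.dc.il8 = st_.dc.il12 = st_.dc.cd70 = 0.2
    s0 = stimulation_signal(st_, ref_params)
    st_.dc.il6 = st_.dc.il8 = st_.dc.il12 = 0.4
    assert stimulation_signal(st_, ref_params) == pytest.approx(2 * s0)
    st_.dc.cd70 = 0.4
    assert stimulation_signal(st_, ref_params) == pytest.approx(4 * s0)


# ---------------------------------------------------------------------------
# T-cell rate law
# ---------------------------------------------------------------------------

def test_memory_influx_hand_value(ref_params):
    """dM/dt = k_diff2*EE + 0.1*k_deg_SLE*SLE = 1 + 2 = 3."""
    p = ref_params.with_overrides({"k_diff2_EE": 0.01, "k_deg_SLE": 0.1})
    t = TCellState(naive=0.0, early_effector=100.0,
                   short_lived_effector=200.0, memory=0.0)
    d = rhs_tcell(t, 0.0, p)
    assert d.memory == pytest.approx(3.0)


def test_memory_constant_without_effectors(ref_params):
    t = TCellState(naive=1e6, early_effector=0.0, short_lived_effector=0.0,
                   memory=0.0)
    d = rhs_tcell(t, 500.0, ref_params)
    assert d.memory == 0.0
    with pytest.raises(ValueError):
        rhs_tcell(t, -1.0, ref_params)


def test_naive_pool_untouched_without_signal(ref_params):
    t = TCellState(naive=1e6, early_effector=0.0, short_lived_effector=0.0,
                   memory=0.0)
    d = rhs_tcell(t, 0.0, ref_params)
    assert d.naive == 0.0 and d.early_effector == 0.0


# ---------------------------------------------------------------------------
# simulation contracts
# ---------------------------------------------------------------------------

def test_null_injection_stays_at_rest(ref_params):
    c0 = DesignConstants(DC_in=0.0)
    scen = Scenario(name="null", stimulus=((0.0, 0.0),))
    traj = dcvax.simulate(scen, ref_params, c0, t_end=100.0)
    rel = np.abs(traj.states - traj.states[0]) / np.maximum(
        np.abs(traj.states[0]), 1e-12)
    assert rel.max() < 1e-6
    assert traj["memory"].max() == 0.0
    assert traj["naive"][0] == c0.T_0


def test_reference_trajectory_invariants(ref_trajectory, ref_params):
    diag = ref_trajectory.diagnostics
    assert diag["max_moiety_drift"] < 1e-6 * ref_params["N_tot"]
    assert diag["min_state"] > -1e-9
    assert not diag["moiety_warning"]
    m = ref_trajectory["memory"]
    assert np.all(np.diff(m) >= -1e-9 * max(m.max(), 1.0))


def test_mass_balance_diagnostic_within_tenth_percent(ref_params, constants,
                                                      scenarios):
    traj = dcvax.simulate(scenarios["normal_dc"], ref_params, constants,
                          grid=np.linspace(0.0, 72.0, 2001))
    assert traj.diagnostics["max_mass_balance_error"] < 1e-3


def test_biodistribution_shapes(ref_params, constants, scenarios):
    """Lung: early peak then drop to a low level; liver: rises then stays;
    blood: decays toward 0; spleen: peak then gradual decline."""
    traj = dcvax.simulate(scenarios["normal_dc"], ref_params, constants,
                          grid=np.linspace(0.0, 72.0, 721))
    lung = traj["dc_lung_count"]
    assert traj.time[lung.argmax()] < 8.0
    assert lung[-1] < 0.05 * lung.max()
    blood = traj["dc_blood_count"]
    assert blood[-1] < 1e-6 * blood[0]
    liver = traj["dc_liver_count"]
    assert liver[-1] == pytest.approx(liver.max(), rel=1e-6)
    spleen = traj["dc_spleen_count"]
    ipk = spleen.argmax()
    assert 0 < ipk < len(spleen) - 1
    assert spleen[-1] < 0.5 * spleen.max()


def test_halved_tolerances_leave_memory_unchanged(ref_params, constants,
                                                  scenarios):
    t1 = dcvax.simulate(scenarios["normal_dc"], ref_params, constants,
                        t_end=200.0, rtol=1e-6, atol=1e-9)
    t2 = dcvax.simulate(scenarios["normal_dc"], ref_params, constants,
                        t_end=200.0, rtol=5e-7, atol=5e-10)
    m1, m2 = t1["memory"][-1], t2["memory"][-1]
    assert abs(m1 - m2) / m2 < 1e-3


def test_caikk_arm_has_higher_ikkb_and_nfkb_exposure(arm_trajectories):
    tn, tc = arm_trajectories["normal_dc"], arm_trajectories["caikk_dc"]
    assert np.all(tc["ikkb"] - tn["ikkb"] >= -1e-12)
    int_n = np.trapezoid(tn["nfkb"], tn.time)
    int_c = np.trapezoid(tc["nfkb"], tc.time)
    assert int_c > int_n


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------

def test_steady_state_memory_no_stimulation(ref_params):
    c0 = DesignConstants(DC_in=0.0)
    scen = Scenario(name="null", stimulus=((0.0, 0.0),))
    res = dcvax.steady_state_memory(scen, ref_params, c0)
    assert res.m_star == 0.0 and res.converged


def test_steady_state_exceeds_200h_and_matches_long_run(ref_params, constants,
                                                        scenarios):
    res = dcvax.steady_state_memory(scenarios["caikk_dc"], ref_params,
                                    constants)
    assert res.converged
    traj = dcvax.simulate(scenarios["caikk_dc"], ref_params, constants,
                          grid=np.array([0.0, 200.0, 16000.0]),
                          rtol=1e-8, atol=1e-11)
    assert res.m_star >= traj["memory"][1]
    assert res.m_star == pytest.approx(traj["memory"][2], rel=1e-2)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def test_scenario_validation():
    with pytest.raises(ParameterValidationError):
        Scenario(name="x", overrides={"bogus": 1.0})
    with pytest.raises(ParameterValidationError):
        Scenario(name="x", stimulus=((0.0, 1.5),))
    with pytest.raises(ParameterValidationError):
        Scenario(name="x", restimulation=(10.0, 5.0))


def test_builtin_scenarios_differ_only_in_ikkb_degradation(scenarios):
    normal, caikk = scenarios["normal_dc"], scenarios["caikk_dc"]
    assert normal.overrides == {}
    assert caikk.overrides == {"k_deg_IKKb": 0.216}


def test_restimulation_resets_dc_pool(ref_params, constants, scenarios):
    scen = scenarios["tcell_invitro_normal"]
    traj = dcvax.simulate(scen, ref_params, constants,
                          grid=np.linspace(0.0, 400.0, 2001))
    blood = traj["dc_blood_count"]
    i168 = np.searchsorted(traj.time, 168.0)
    assert blood[i168] > 0.5 * blood[0]       # fresh batch at one week
    assert blood[i168 - 1] < 1e-3 * blood[0]  # pool was depleted before
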