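"""Contraction model: element curves, force balance, equilibria, simulation."""
import dataclasses

import numpy as np
import pytest

from mtuenergy.contraction import (
    contraction_derivative,
    element_forces,
    initial_fiber_length,
    simulate_mtu,
    SolverConfig,
)
from mtuenergy.errors import StateError
from mtuenergy.signals import KinematicsSeries, StimulationSeries


def test_isometric_force_at_optimum_is_fmax(ref_params):
    p = ref_params
    # place the fiber at optimum with the tendon stretched to carry Fmax
    lsee = p.lsee_0
    from mtuenergy.contraction import _engine
    e = _engine(p)
    # invert the SEE curve for the stretch carrying exactly Fmax
    stretch = e.l_see_nll - p.lsee_0 + (p.fmax - e.df_see0) / e.k_see_l
    fb = element_forces(p.lce_opt, p.lce_opt + p.lsee_0 + stretch, 0.0, 0.0,
                        1.0, p)
    assert fb.F_CE == pytest.approx(p.fmax, rel=1e-12)
    assert fb.F_SEE == pytest.approx(p.fmax, rel=1e-3)


def test_activity_scales_isometric_force_linearly(ref_params):
    p = ref_params
    fb = element_forces(p.lce_opt, p.lce_opt + p.lsee_0, 0.0, 0.0, 0.5, p)
    assert fb.F_CE == pytest.approx(0.5 * p.fmax, rel=1e-12)


def test_slack_tendon_carries_no_force(ref_params):
    p = ref_params
    fb = element_forces(p.lce_opt, p.lce_opt + 0.9 * p.lsee_0, 0.0, 0.0, 0.5, p)
    assert fb.F_SEE == 0.0


def test_fiber_longer_than_mtu_rejected(ref_params):
    with pytest.raises(StateError):
        element_forces(0.3, 0.2, 0.0, 0.0, 0.5, ref_params)


def test_equilibrium_state_has_zero_fiber_velocity(ref_params):
    p = ref_params
    lmtu0 = 0.311
    lce0 = initial_fiber_length(lmtu0, 0.005, p)
    assert abs(contraction_derivative(lce0, lmtu0, 0.0, 0.005, p)) < 1e-9


def test_raising_activity_shortens_the_fiber(ref_params):
    p = ref_params
    lmtu0 = 0.311
    lce0 = initial_fiber_length(lmtu0, 0.005, p)
    assert contraction_derivative(lce0, lmtu0, 0.0, 0.05, p) < 0.0


def test_unloaded_shortening_speed_matches_hill_relation(ref_params):
    """At zero load, full activity and optimal length the Hill hyperbola
    yields |l̇_CE| = (B_rel,0/A_rel,0)·l_CE_opt (the activity factors of both
    constants equal one at a = 1)."""
    p = ref_params
    curves = dataclasses.replace(p.curves, f_pee=0.0, d_sde=0.0)
    p0 = dataclasses.replace(p, curves=curves)
    # slack tendon -> zero external load; PEE and SDE disabled
    v = contraction_derivative(p.lce_opt, p.lce_opt + 0.9 * p.lsee_0, 0.0, 1.0, p0)
    assert v == pytest.approx(-p.brel0 / p.arel0 * p.lce_opt, rel=1e-9)


def test_force_velocity_monotonicity(ref_params):
    """For fixed (l_CE, a) the CE force is non-increasing with shortening speed."""
    p = ref_params
    speeds = np.linspace(0.0, -0.15, 20)
    forces = [element_forces(p.lce_opt, p.lce_opt + p.lsee_0, v, 0.0, 0.8, p).F_CE
              for v in speeds]
    assert np.all(np.diff(forces) <= 1e-12)


def test_eccentric_force_exceeds_isometric(ref_params):
    p = ref_params
    iso = element_forces(p.lce_opt, p.lce_opt + p.lsee_0, 0.0, 0.0, 0.8, p).F_CE
    ecc = element_forces(p.lce_opt, p.lce_opt + p.lsee_0, 0.02, 0.0, 0.8, p).F_CE
    assert iso < ecc <= p.curves.f_ecc * iso + 1e-9


def test_initial_fiber_length_study_conditions(ref_params):
    """Static equilibrium at the study's initial MTU length and activity."""
    p = ref_params
    lce0 = initial_fiber_length(0.311, 0.005, p)
    assert lce0 == pytest.approx(0.052, abs=1e-3)
    fb = element_forces(lce0, 0.311, 0.0, 0.0, 0.005, p)
    assert abs(fb.F_CE + fb.F_PEE - fb.F_SEE) < 1e-6 * p.fmax


def test_initial_fiber_length_relaxed_rest(ref_params):
    """With everything at rest the equilibrium sits at the slack lengths."""
    p = ref_params
    lce0 = initial_fiber_length(p.lce_opt + p.lsee_0, 0.001, p)
    assert lce0 == pytest.approx(p.lce_opt, abs=1.5e-3)


def _constant_inputs(lmtu, u, t_end=2.0, n=51):
    t = np.linspace(0.0, t_end, n)
    kin = KinematicsSeries(t=t, lmtu=np.full_like(t, lmtu),
                           lmtu_dot=np.zeros_like(t))
    stim = StimulationSeries(t=t, u=np.full_like(t, u))
    return kin, stim


def test_constant_inputs_converge_to_static_equilibrium(ref_params):
    p = ref_params
    u0 = 0.2
    kin, stim = _constant_inputs(0.313, u0, t_end=2.0)
    traj = simulate_mtu(kin, stim, p).data
    lce_eq = initial_fiber_length(0.313, u0, p)
    assert traj["a"].iloc[-1] == pytest.approx(u0, abs=1e-4)
    assert traj["lce"].iloc[-1] == pytest.approx(lce_eq, abs=1e-5)
    assert abs(traj["lce_dot"].iloc[-1]) < 1e-6


def test_rest_inputs_give_constant_forces(ref_params):
    kin, stim = _constant_inputs(0.311, 0.001, t_end=1.0)
    traj = simulate_mtu(kin, stim, ref_params).data
    assert np.ptp(traj["F_MTU"].to_numpy()) < 1e-3 * ref_params.fmax


def test_force_balance_residual_along_trajectory(sim_result, ref_params):
    df = sim_result.trajectory
    resid = (df["F_CE"] + df["F_PEE"] - df["F_SEE"] - df["F_SDE"]).abs()
    assert resid.max() < 1e-6 * ref_params.fmax


def test_periodic_steady_state(ref_params, short_protocol):
    """After the transient, F_MTU repeats cycle-to-cycle within 1% of range.

    Integrated at a tightened tolerance so that solver jitter (comparable to
    1% of the force range at the default 1e-4) does not mask the property.
    """
    import dataclasses

    from mtuenergy.pipeline import SimulationConfig, run_simulation
    from mtuenergy.synthetic import generate_pedal_angle, generate_stimulation

    prot = dataclasses.replace(short_protocol, duration_load=16.0)
    cfg = SimulationConfig(rtol=1e-6, atol_lce=1e-9, atol_a=1e-8,
                           fit_window=10.0)
    df = run_simulation(ref_params, generate_pedal_angle(prot),
                        generate_stimulation(prot).stim, cfg,
                        t_end=15.0).trajectory
    period = short_protocol.period
    t = df["t"].to_numpy()
    f = df["F_MTU"].to_numpy()
    grid = np.arange(0.0, period, 0.01)
    c1 = np.interp(10 * period + grid, t, f)   # second-to-last full cycle
    c2 = np.interp(11 * period + grid, t, f)   # last full cycle
    scale = np.ptp(f[(t >= 5.0) & (t <= 15.0)])
    assert np.max(np.abs(c1 - c2)) < 0.01 * scale
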