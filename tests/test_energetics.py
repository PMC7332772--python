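"""Heat-rate and work-rate accounting: coefficients, scaling, identities."""
import dataclasses

import numpy as np
import pytest

from mtuenergy.energetics import (
    effective_activation,
    evaluate_trajectory,
    heat_activation_maintenance,
    heat_shortening_lengthening,
    mechanical_work_rate,
    total_energy_rate,
)


@pytest.mark.parametrize("u, a, expected", [
    (1.0, 1.0, 1.0),
    (0.2, 0.6, 0.4),   # deactivating: (u+a)/2
    (0.6, 0.2, 0.6),   # activating: u
])
def test_effective_activation_blend(u, a, expected):
    assert effective_activation(u, a) == pytest.approx(expected)


def test_am_heat_nominal_rates(ref_params):
    p = ref_params
    # fully active mixed muscle at optimal length: 1.28·45 + 25 = 82.6 W/kg
    assert heat_activation_maintenance(p.lce_opt, 1.0, 1.0, p) == \
        pytest.approx(82.6, abs=1e-9)
    # resting floor scales as A^0.6
    assert heat_activation_maintenance(p.lce_opt, 0.001, 0.001, p) == \
        pytest.approx(82.6 * 0.001 ** 0.6, rel=1e-9)
    # slow-twitch limit
    p_slow = dataclasses.replace(p, r_fib=0.0)
    assert heat_activation_maintenance(p.lce_opt, 1.0, 1.0, p_slow) == \
        pytest.approx(25.0, abs=1e-9)


def test_am_heat_reduced_above_optimal_length(ref_params):
    p = ref_params
    at_opt = heat_activation_maintenance(p.lce_opt, 0.5, 0.5, p)
    above = heat_activation_maintenance(1.3 * p.lce_opt, 0.5, 0.5, p)
    assert above < at_opt


def test_shortening_heat_zero_at_rest_and_nonnegative(ref_params):
    p = ref_params
    assert heat_shortening_lengthening(0.0, p.lce_opt, 0.5, 0.5, p) == 0.0
    for v in (-0.05, 0.05):
        assert heat_shortening_lengthening(v, p.lce_opt, 0.3, 0.3, p) >= 0.0


def test_shortening_heat_scales_with_activation_squared(ref_params):
    p = ref_params
    r1 = heat_shortening_lengthening(-0.03, p.lce_opt, 0.2, 0.2, p)
    r2 = heat_shortening_lengthening(-0.03, p.lce_opt, 0.4, 0.4, p)
    assert r2 == pytest.approx(4.0 * r1, rel=1e-9)
    # lengthening is linear in activation
    l1 = heat_shortening_lengthening(0.03, p.lce_opt, 0.2, 0.2, p)
    l2 = heat_shortening_lengthening(0.03, p.lce_opt, 0.4, 0.4, p)
    assert l2 == pytest.approx(2.0 * l1, rel=1e-9)


def test_mechanical_work_rate_sign_and_value():
    # shortening at 5 cm/s against 100 N with the study muscle mass
    assert mechanical_work_rate(100.0, -0.05, 0.3587) == \
        pytest.approx(13.9392, abs=5e-4)
    assert mechanical_work_rate(100.0, 0.0, 0.3587) == 0.0
    assert mechanical_work_rate(100.0, 0.02, 0.3587) < 0.0  # lengthening absorbs


def test_total_rate_decomposition_and_clamp(ref_params):
    p = ref_params
    br = total_energy_rate(p.lce_opt, -0.02, 0.3, 0.3, 150.0, p)
    assert br.E_dot == pytest.approx(br.h_AM + br.h_SL + br.w_CE)
    # strong lengthening absorbs more work than the heat terms release
    br2 = total_energy_rate(p.lce_opt, 0.5, 0.001, 0.001, 400.0, p)
    assert br2.h_AM + br2.h_SL + br2.w_CE < 0.0
    assert br2.E_dot == 0.0


def test_mass_specific_heat_independent_of_fmax(ref_params):
    """Doubling Fmax must not change the per-kg heat rates (unit guard)."""
    p = ref_params
    p2 = dataclasses.replace(p, fmax=2 * p.fmax)
    assert heat_activation_maintenance(p.lce_opt, 0.4, 0.4, p2) == \
        pytest.approx(heat_activation_maintenance(p.lce_opt, 0.4, 0.4, p))
    assert heat_shortening_lengthening(-0.02, p.lce_opt, 0.4, 0.4, p2) == \
        pytest.approx(heat_shortening_lengthening(-0.02, p.lce_opt, 0.4, 0.4, p))


def test_trajectory_energy_identity_and_monotonicity(sim_result, ref_params):
    df = sim_result.trajectory
    clamped = np.maximum(df["h_AM"] + df["h_SL"] + df["w_CE"], 0.0)
    assert np.allclose(df["E_dot"], clamped, atol=1e-12)
    assert np.all(np.diff(df["E_cum"]) >= -1e-12)


def test_trajectory_work_consistent_with_force_velocity(sim_result, ref_params):
    """ẇ_CE along the trajectory equals −F_CE·l̇_CE/M sample by sample."""
    df = sim_result.trajectory
    expected = -df["F_CE"] * df["lce_dot"] / ref_params.mass
    assert np.allclose(df["w_CE"], expected, atol=1e-10)


def test_resting_floor_is_small_and_constant(ref_params):
    """No motion, stimulation at the lower bound: Ė is a small constant."""
    from mtuenergy.contraction import simulate_mtu
    from mtuenergy.signals import KinematicsSeries, StimulationSeries

    t = np.linspace(0.0, 2.0, 80)
    kin = KinematicsSeries(t=t, lmtu=np.full_like(t, 0.311),
                           lmtu_dot=np.zeros_like(t))
    stim = StimulationSeries(t=t, u=np.full_like(t, 0.001))
    df = evaluate_trajectory(simulate_mtu(kin, stim, ref_params).data, ref_params)
    tail = df[df["t"] > 0.5]["E_dot"]
    assert tail.max() < 2.0            # W/kg, far below exercise rates
    assert np.ptp(tail.to_numpy()) < 0.01
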