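"""Parameter derivation from morphometry: formulas, invariants, errors."""
import dataclasses
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mtuenergy.errors import ConfigurationError, DomainError
from mtuenergy.parameters import (
    MorphometryInput,
    activation_time_constants,
    compute_fmax,
    compute_mass,
    compute_tendon_slack,
    derive_parameters,
    hill_constants,
    load_morphometry,
    reference_parameters,
)


@pytest.mark.parametrize(
    "sigma, V, lce_opt, alpha, expected, tol",
    [
        # the study muscle: 0.25 MPa, 379.89 cm^3, 57.4 mm fibers, 27° pennation
        (0.25e6, 379.89e-6, 0.0574, 27.0, 1474.0, 0.5),
        # zero pennation drops the cosine
        (0.25e6, 200e-6, 0.05, 0.0, 1000.0, 1e-9),
        (2.0e5, 3.0e-4, 0.06, 0.0, 2.0e5 * 3.0e-4 / 0.06, 1e-9),
    ],
)
def test_fmax_formula(sigma, V, lce_opt, alpha, expected, tol):
    assert compute_fmax(sigma, V, lce_opt, alpha) == pytest.approx(expected, abs=tol)


@pytest.mark.parametrize("bad_kwargs", [
    dict(sigma=0.25e6, V=1e-4, lCE_opt=-0.05, alpha=10.0),
    dict(sigma=0.25e6, V=1e-4, lCE_opt=0.05, alpha=90.0),
    dict(sigma=-1.0, V=1e-4, lCE_opt=0.05, alpha=10.0),
])
def test_fmax_domain_errors(bad_kwargs):
    with pytest.raises(DomainError):
        compute_fmax(bad_kwargs["sigma"], bad_kwargs["V"],
                     bad_kwargs["lCE_opt"], bad_kwargs["alpha"])


def test_tendon_slack_values():
    # the printed derivation (0.257 m) and table value (0.2573 m) differ at
    # sub-millimeter rounding; the exact difference is 0.2576 m
    assert compute_tendon_slack(0.315, 0.0574) == pytest.approx(0.2576, abs=5e-4)
    assert compute_tendon_slack(0.40, 0.10) == pytest.approx(0.30, abs=1e-15)
    with pytest.raises(DomainError):
        compute_tendon_slack(0.315, 0.315)


def test_mass_is_volume_times_density():
    assert compute_mass(1e-3, 1000.0) == pytest.approx(1.0)
    assert compute_mass(379.89e-6, 1059.7) == pytest.approx(0.40257, abs=1e-4)
    assert compute_mass(2e-4, 1059.7) == pytest.approx(0.21194, abs=1e-5)


@pytest.mark.parametrize("r_fib, expected", [
    (0.45, (0.28, 3.36)),
    (0.0, (0.1, 1.2)),
    (1.0, (0.5, 6.0)),
])
def test_hill_constants(r_fib, expected):
    arel0, brel0 = hill_constants(r_fib)
    assert arel0 == pytest.approx(expected[0])
    assert brel0 == pytest.approx(expected[1])


@pytest.mark.parametrize("r_fib, tau_ms", [
    (0.45, (58.85, 64.8)),   # prints as 58.8 / 64.8 ms for the study subject
    (0.0, (80.0, 90.0)),
    (1.0, (33.0, 34.0)),
])
def test_activation_time_constants(r_fib, tau_ms):
    tau_act, tau_deact = activation_time_constants(r_fib)
    assert tau_act * 1000 == pytest.approx(tau_ms[0], abs=1e-9)
    assert tau_deact * 1000 == pytest.approx(tau_ms[1], abs=1e-9)


@pytest.mark.parametrize("fn", [hill_constants, activation_time_constants])
@pytest.mark.parametrize("r_fib", [-0.01, 1.01])
def test_fiber_ratio_domain(fn, r_fib):
    with pytest.raises(DomainError):
        fn(r_fib)


def test_derive_parameters_reference(ref_morph):
    p = derive_parameters(ref_morph)
    assert p.fmax == pytest.approx(1474.0, abs=0.5)
    assert p.lsee_0 == pytest.approx(0.2576, abs=5e-4)
    assert p.arel0 == pytest.approx(0.28)
    assert p.tau_act <= p.tau_deact
    assert p.lsee_0 == pytest.approx(ref_morph.lMTU_rest - ref_morph.lCE_opt,
                                     abs=1e-12)


def test_derive_parameters_is_pure(ref_morph):
    assert derive_parameters(ref_morph) == derive_parameters(ref_morph)


def test_reference_parameters_use_tabulated_mass():
    assert reference_parameters().mass == pytest.approx(0.3587)


def test_invalid_morphometry_rejected():
    with pytest.raises(DomainError):
        MorphometryInput(V=1e-4, lMTU_rest=0.1, lCE_opt=0.2, alpha=10.0,
                         lever_arm=0.06, sigma=0.25e6, rho=1059.7, r_fib=0.45)


def test_unknown_override_rejected(ref_morph):
    with pytest.raises(ConfigurationError):
        derive_parameters(ref_morph, overrides={"not_a_field": 1.0})


@given(
    v=st.floats(1e-5, 1e-3), sigma=st.floats(1e5, 5e5),
    lce=st.floats(0.02, 0.1), alpha=st.floats(0.0, 80.0),
)
def test_fmax_monotonicity(v, sigma, lce, alpha):
    base = compute_fmax(sigma, v, lce, alpha)
    assert compute_fmax(sigma, v * 1.1, lce, alpha) > base
    assert compute_fmax(sigma * 1.1, v, lce, alpha) > base
    assert compute_fmax(sigma, v, lce * 1.1, alpha) < base
    if alpha < 80.0:
        assert compute_fmax(sigma, v, lce, min(alpha + 5.0, 89.0)) < base


@given(r=st.floats(0.0, 1.0))
def test_hill_and_tau_affine_in_fiber_ratio(r):
    arel0, brel0 = hill_constants(r)
    assert arel0 == pytest.approx(0.1 + 0.4 * r)
    assert brel0 == pytest.approx(12.0 * arel0)
    tau_act, tau_deact = activation_time_constants(r)
    assert tau_act == pytest.approx((80.0 - 0.47 * 100 * r) / 1000)
    assert tau_deact == pytest.approx((90.0 - 0.56 * 100 * r) / 1000)


def test_load_morphometry_roundtrip(tmp_path, ref_morph):
    doc = tmp_path / "morph.yaml"
    doc.write_text(
        "V: 379.89e-6\nlMTU_rest: 0.315\nlCE_opt: 0.0574\nalpha: 27\n"
        "lever_arm: 0.064\nsigma: 0.25e6\nrho: 1059.7\nr_fib: 0.45\n"
        "mass: 0.3587\n"
    )
    morph, overrides = load_morphometry(doc)
    assert morph == ref_morph
    assert overrides == {"mass": 0.3587}
    p = derive_parameters(morph, overrides=overrides)
    assert p.mass == pytest.approx(0.3587)

    bad = tmp_path / "bad.yaml"
    bad.write_text(doc.read_text() + "unknown_key: 1\n")
    with pytest.raises(ConfigurationError):
        load_morphometry(bad)
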