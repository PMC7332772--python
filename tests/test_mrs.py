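"""PCr-based energy estimation: quantification, conversion, window, fit."""
import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mtuenergy.errors import ConfigurationError, DomainError, WindowError
from mtuenergy.mrs import (
    EnthalpyConstants,
    PcrSeries,
    detect_validation_window,
    energy_rate_from_pcr,
    fit_energy_rate,
    pcr_rate,
    quantify_pcr,
    read_pcr_file,
)
from mtuenergy.synthetic import SyntheticProtocol, generate_pcr_series


def _series(t, pcr, ph=None):
    return PcrSeries(t=np.asarray(t, float), pcr=np.asarray(pcr, float),
                     ph=None if ph is None else np.asarray(ph, float))


@pytest.mark.parametrize("ipcr, igatp, expected", [
    (1.0, 1.0, 8.2),
    (4.0, 1.0, 32.8),
    (0.0, 1.0, 0.0),
])
def test_quantify_pcr(ipcr, igatp, expected):
    assert quantify_pcr(ipcr, igatp) == pytest.approx(expected)


def test_quantify_pcr_rejects_nonpositive_reference():
    with pytest.raises(DomainError):
        quantify_pcr(1.0, 0.0)


def test_pcr_rate_forward_differences():
    mid, rates = pcr_rate(_series([0.0, 5.0], [30.0, 25.0]))
    assert mid.tolist() == [2.5]
    assert rates[0] == pytest.approx(-1.0)
    # constant and linear series
    _, r0 = pcr_rate(_series([0, 5, 10], [20, 20, 20]))
    assert np.allclose(r0, 0.0)
    _, rlin = pcr_rate(_series([0, 5, 10], [30, 28, 26]))
    assert np.allclose(rlin, -0.4)


def test_conversion_factor_is_14_28():
    c = EnthalpyConstants()
    assert c.factor == pytest.approx(14.28)
    assert energy_rate_from_pcr(-1.0) == pytest.approx(14.28)
    assert energy_rate_from_pcr(0.0) == 0.0
    assert energy_rate_from_pcr(-0.35) == pytest.approx(4.998)


@given(slope=st.floats(-2.0, 0.0), scale=st.floats(0.1, 5.0))
def test_conversion_is_linear(slope, scale):
    assert energy_rate_from_pcr(slope * scale) == \
        pytest.approx(scale * energy_rate_from_pcr(slope), rel=1e-12)


def test_window_detection_at_ph_maximum():
    t = np.arange(0.0, 60.0, 5.0)
    ph = np.where(t <= 25.0, 7.05 + 0.002 * t, 7.10 - 0.004 * (t - 25.0))
    s = _series(t, np.full_like(t, 30.0), ph)
    t0, t1 = detect_validation_window(s)
    assert t0 == 0.0
    assert t1 == pytest.approx(25.0, abs=5.0)


def test_window_default_without_ph():
    t = np.arange(0.0, 40.0, 5.0)
    assert detect_validation_window(_series(t, np.full_like(t, 30.0))) == (0.0, 25.0)


def test_window_clipped_for_monotone_ph():
    t = np.arange(0.0, 120.0, 5.0)
    ph = 7.05 + 0.0005 * t  # keeps rising to the end of the record
    with pytest.warns(UserWarning, match="clipping"):
        _, t1 = detect_validation_window(_series(t, np.full_like(t, 30.0), ph))
    assert t1 == 60.0


def test_noiseless_fit_recovers_generating_rate_exactly():
    prot = SyntheticProtocol(true_rate=5.0, noise_sd_pcr=0.0)
    est = fit_energy_rate(generate_pcr_series(prot))
    assert est.rate == pytest.approx(5.0, rel=1e-9)
    assert est.ci95_halfwidth < 1e-9
    assert est.n_points >= 3


def test_constant_pcr_gives_zero_rate():
    t = np.arange(0.0, 40.0, 5.0)
    est = fit_energy_rate(_series(t, np.full_like(t, 30.0)), window=(0.0, 25.0))
    assert est.rate == 0.0


def test_fit_invariant_to_pcr_offset():
    prot = SyntheticProtocol(true_rate=5.0, noise_sd_pcr=0.0)
    s = generate_pcr_series(prot)
    shifted = PcrSeries(t=s.t, pcr=s.pcr + 7.0, ph=s.ph, dt=s.dt)
    e1 = fit_energy_rate(s, window=(0.0, 25.0))
    e2 = fit_energy_rate(shifted, window=(0.0, 25.0))
    assert e2.rate == pytest.approx(e1.rate, rel=1e-12)


def test_ci_coverage_under_noise():
    """The 95% CI covers the generating rate in ≈95% of noisy replicates."""
    prot = SyntheticProtocol(true_rate=5.0, noise_sd_pcr=0.5)
    hits = 0
    n_rep = 200
    for seed in range(n_rep):
        s = generate_pcr_series(dataclasses.replace(prot, seed=seed))
        est = fit_energy_rate(s, window=(0.0, 25.0))
        hits += abs(est.rate - 5.0) <= est.ci95_halfwidth
    assert 0.90 <= hits / n_rep <= 0.99


def test_fit_refuses_to_extrapolate_past_detected_window():
    prot = SyntheticProtocol(true_rate=5.0, noise_sd_pcr=0.0)
    s = generate_pcr_series(prot)
    with pytest.raises(WindowError):
        fit_energy_rate(s, window=(0.0, 60.0))
    est = fit_energy_rate(s, window=(0.0, 60.0), allow_beyond_window=True)
    assert est.rate < 5.0   # underestimation past the creatine-kinase phase


def test_fit_needs_three_samples():
    with pytest.raises(ConfigurationError):
        fit_energy_rate(_series([0.0, 5.0], [30.0, 28.0]), window=(0.0, 10.0))


def test_read_pcr_file_layouts(tmp_path):
    f1 = tmp_path / "conc.csv"
    f1.write_text("t,pcr,ph\n0,30,7.05\n5,28,7.06\n10,26,7.07\n")
    s1 = read_pcr_file(f1)
    assert s1.pcr.tolist() == [30.0, 28.0, 26.0]
    assert s1.ph is not None

    f2 = tmp_path / "intens.csv"
    f2.write_text("t,I_PCr,I_gammaATP\n0,4.0,1.0\n5,3.5,1.0\n")
    s2 = read_pcr_file(f2)
    assert s2.pcr.tolist() == [32.8, pytest.approx(28.7)]

    f3 = tmp_path / "bad.csv"
    f3.write_text("t,foo\n0,1\n")
    with pytest.raises(ConfigurationError):
        read_pcr_file(f3)
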