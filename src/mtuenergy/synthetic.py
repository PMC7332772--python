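"""Synthetic study inputs with the structure the analysis assumes.

The study's recordings (pedal angle, surface EMG, ³¹P-MRS series of a single
subject) are not deposited, so every pipeline stage is exercised against
generated inputs that reproduce the *protocol*: 0.8 Hz pedaling between 0°
and 25° for 3 min, burst-like stimulation at ~20% effort, and a [PCr] record
with a linear depletion phase (the validation phase, default 25 s) followed
by a glycolysis-dominated phase in which the depletion levels off and the pH
turns from rising (7.05 → 7.10, proton-consuming creatine kinase reaction)
to falling.  In the validation phase the PCr generator applies the exact
inverse of the enthalpy conversion, so generator + estimator form an exact
round-trip pair in the noiseless case.

All generators are pure functions of (protocol, seed).
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import ConfigurationError, DomainError
from .mrs import EnthalpyConstants, PcrSeries
from .signals import AngleSeries, StimulationSeries

__all__ = [
    "SyntheticProtocol",
    "SyntheticEmg",
    "generate_pedal_angle",
    "generate_stimulation",
    "generate_pcr_series",
    "write_synthetic_inputs",
]


@dataclass(frozen=True)
class SyntheticProtocol:
    """Exercise protocol and generator settings (defaults = study conditions)."""

    cadence: float = 0.8            # Hz, pedaling frequency
    angle_min: float = 0.0          # deg
    angle_max: float = 25.0         # deg
    initial_angle: float = 3.13     # deg, pedal angle at exercise onset
    duration_load: float = 180.0    # s, exercise phase
    duration_rest_pre: float = 120.0  # s, resting spectra before onset
    emg_peak: float = 0.10          # peak of the rectified-EMG envelope at
    #                                 ~20% effort: EMG amplitude scales about
    #                                 linearly with task force, and normalizing
    #                                 to the MVC *maximum* (a noise peak ~2x
    #                                 the burst envelope) halves the level again
    emg_burst_duty: float = 0.40    # fraction of each cycle with active burst
    angle_fs: float = 100.0         # Hz, angle sampling
    emg_fs: float = 2000.0          # Hz, raw EMG sampling
    mvc_reference: float = 1.0      # MVC amplitude of the raw EMG (arbitrary units)
    mrs_dt: float = 5.0             # s, MRS sampling interval
    pcr_baseline: float = 32.0      # mmol/l (assumption; estimates are offset-invariant)
    true_rate: float = 5.8          # J kg⁻¹ s⁻¹, generating expenditure rate
    t_glycolysis: float = 25.0      # s, end of the PCr-dominated phase
    tau_takeover: float = 25.0      # s, post-window depletion decay constant
    ph_rest: float = 7.05
    ph_peak: float = 7.10
    ph_end: float = 6.75            # pH reached at the end of the load phase
    noise_sd_pcr: float = 0.5       # mmol/l
    noise_sd_ph: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.cadence <= 0:
            raise DomainError("cadence must be strictly positive")
        if not 0.0 < self.emg_burst_duty < 1.0:
            raise DomainError("emg_burst_duty must lie in (0, 1)")
        if self.noise_sd_pcr < 0 or self.noise_sd_ph < 0:
            raise DomainError("noise levels must be non-negative")
        if not self.angle_min <= self.initial_angle <= self.angle_max:
            raise DomainError("initial angle outside the angle range")
        if self.emg_peak < 0 or self.emg_peak > 1:
            raise DomainError("emg_peak must lie in [0, 1]")

    @property
    def period(self) -> float:
        return 1.0 / self.cadence


def generate_pedal_angle(protocol: SyntheticProtocol) -> AngleSeries:
    """Raised-cosine pedaling trajectory between the protocol's angle extrema.

    φ(t) = min + amp·(1 − cos(2π·f·t + ψ))/2 with the phase ψ chosen so that
    the record starts at the configured initial angle with φ̇(0) ≥ 0.
    """
    p = protocol
    t = np.arange(0.0, p.duration_load, 1.0 / p.angle_fs)
    amp = p.angle_max - p.angle_min
    if amp <= 0:
        raise DomainError("angle_max must exceed angle_min")
    frac0 = (p.initial_angle - p.angle_min) / amp
    psi = math.acos(1.0 - 2.0 * frac0)  # in [0, pi] -> rising start
    phi = p.angle_min + 0.5 * amp * (1.0 - np.cos(2.0 * math.pi * p.cadence * t + psi))
    return AngleSeries(t=t, phi=phi)


@dataclass
class SyntheticEmg:
    """Ground-truth stimulation plus the raw EMG-like signal it modulates."""

    stim: StimulationSeries          # ideal u(t) (burst envelope)
    t_raw: np.ndarray                # raw EMG sample times (s)
    raw: np.ndarray                  # raw EMG-like signal (signed)
    mvc_reference: float
    burst_count: int


def generate_stimulation(protocol: SyntheticProtocol) -> SyntheticEmg:
    """Per-cycle burst stimulation with a band-limited-noise raw EMG carrier.

    Each pedaling cycle carries one Hann-shaped burst of duration
    ``emg_burst_duty/cadence`` peaking at ``emg_peak``, placed at the start of
    the cycle (the pedal-push, MTU-shortening phase).  The raw signal is
    band-limited (10–500 Hz) Gaussian noise amplitude-modulated so that its
    local RMS equals the envelope times the MVC reference; a moving-RMS
    envelope of the rectified, normalized signal therefore recovers the
    ground-truth u(t).
    """
    p = protocol
    rng = np.random.default_rng(p.seed)
    t = np.arange(0.0, p.duration_load, 1.0 / p.emg_fs)
    period = p.period
    burst_dur = p.emg_burst_duty * period
    phase = np.mod(t, period)
    in_burst = phase < burst_dur
    envelope = np.where(
        in_burst,
        p.emg_peak * 0.5 * (1.0 - np.cos(2.0 * math.pi * phase / burst_dur)),
        0.0,
    )
    burst_count = int(round(p.cadence * p.duration_load))

    noise = rng.standard_normal(t.size)
    if p.emg_fs > 1100.0:  # band-pass only where the band fits under Nyquist
        sos = butter(4, [10.0, 500.0], btype="bandpass", fs=p.emg_fs, output="sos")
        noise = sosfiltfilt(sos, noise)
    noise /= np.sqrt(np.mean(noise * noise))  # unit RMS carrier
    raw = envelope * p.mvc_reference * noise
    stim = StimulationSeries(t=t, u=np.clip(envelope, 0.0, 1.0))
    return SyntheticEmg(stim=stim, t_raw=t, raw=raw,
                        mvc_reference=p.mvc_reference, burst_count=burst_count)


def generate_pcr_series(protocol: SyntheticProtocol,
                        constants: EnthalpyConstants | None = None) -> PcrSeries:
    """[PCr] and pH record sampled every ``mrs_dt`` seconds.

    Validation phase (0 ≤ t < t_glycolysis): [PCr] falls linearly at
    ``true_rate / (ΔH_ATP·c_vol→mass)`` mmol l⁻¹ s⁻¹ — the exact inverse of
    the estimator's conversion.  Afterwards the depletion slope decays
    exponentially toward a plateau (phenomenological glycolytic/oxidative
    takeover).  pH rises linearly from rest to its peak over the validation
    phase, then falls.  Gaussian noise (sd ``noise_sd_pcr``) is added to
    [PCr], which is clipped at 0.
    """
    p = protocol
    constants = constants or EnthalpyConstants()
    if p.true_rate < 0:
        raise DomainError("true_rate must be non-negative")
    slope = p.true_rate / constants.factor  # mmol/l per s
    if p.pcr_baseline - slope * p.t_glycolysis < 0:
        raise ConfigurationError(
            "protocol depletes [PCr] below zero within the validation phase")
    rng = np.random.default_rng(p.seed + 1)

    t = np.arange(-p.duration_rest_pre, p.duration_load + 0.5 * p.mrs_dt, p.mrs_dt)
    pcr = np.full(t.size, p.pcr_baseline)
    load = t >= 0.0
    tv = np.minimum(t[load], p.t_glycolysis)
    pcr_load = p.pcr_baseline - slope * tv
    # past the validation phase the depletion slope decays exponentially
    late = t[load] > p.t_glycolysis
    te = t[load][late] - p.t_glycolysis
    pcr_load[late] -= slope * p.tau_takeover * (1.0 - np.exp(-te / p.tau_takeover))
    pcr[load] = pcr_load

    ph = np.full(t.size, p.ph_rest)
    rise = load & (t <= p.t_glycolysis)
    ph[rise] = p.ph_rest + (p.ph_peak - p.ph_rest) * t[rise] / p.t_glycolysis
    fall = t > p.t_glycolysis
    fall_span = max(p.duration_load - p.t_glycolysis, p.mrs_dt)
    ph[fall] = p.ph_peak - (p.ph_peak - p.ph_end) * (t[fall] - p.t_glycolysis) / fall_span

    if p.noise_sd_pcr > 0:
        pcr = pcr + rng.normal(0.0, p.noise_sd_pcr, t.size)
    if p.noise_sd_ph > 0:
        ph = ph + rng.normal(0.0, p.noise_sd_ph, t.size)
    pcr = np.clip(pcr, 0.0, None)
    ph = np.clip(ph, 6.0, 7.6)
    return PcrSeries(t=t, pcr=pcr, ph=ph, dt=p.mrs_dt)


def write_synthetic_inputs(protocol: SyntheticProtocol, out_dir: str | Path,
                           constants: EnthalpyConstants | None = None) -> dict:
    """Write angle, EMG and PCr input files plus a ground-truth JSON.

    Returns the ground-truth record (true rate, seed, protocol echo, file
    names).  All outputs are delimited text.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    angle = generate_pedal_angle(protocol)
    emg = generate_stimulation(protocol)
    pcr = generate_pcr_series(protocol, constants)

    np.savetxt(out / "pedal_angle.csv",
               np.column_stack([angle.t, angle.phi]),
               delimiter=",", header="t,phi_deg", comments="", fmt="%.6g")
    np.savetxt(out / "emg_raw.csv",
               np.column_stack([emg.t_raw, emg.raw]),
               delimiter=",", header="t,emg", comments="", fmt="%.6g")
    np.savetxt(out / "stimulation_truth.csv",
               np.column_stack([emg.stim.t, emg.stim.u]),
               delimiter=",", header="t,u", comments="", fmt="%.6g")
    np.savetxt(out / "pcr.csv",
               np.column_stack([pcr.t, pcr.pcr, pcr.ph]),
               delimiter=",", header="t,pcr,ph", comments="", fmt="%.6g")
    truth = {
        "true_rate": protocol.true_rate,
        "seed": protocol.seed,
        "mvc_reference": emg.mvc_reference,
        "burst_count": emg.burst_count,
        "protocol": asdict(protocol),
        "files": ["pedal_angle.csv", "emg_raw.csv", "stimulation_truth.csv", "pcr.csv"],
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth
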