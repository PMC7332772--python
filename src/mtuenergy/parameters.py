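"""Subject-specific muscle parameter derivation.

Every parameter of the contraction/activation/energetics model of the
M. gastrocnemius medialis derives from a small morphometric record (muscle
volume, optimal fiber length, pennation angle, MTU rest length, ankle moment
arm — all measurable from anatomical MRI) plus literature tissue constants
(maximum muscle stress σ, tissue density ρ, fast-twitch fiber ratio r_fib):

* maximum isometric force      Fmax   = σ·V/l_CE_opt·cos(α)
* tendon slack length          l_SEE,0 = l_MTU(φ=0°) − l_CE_opt
* muscle mass                  M      = V·ρ
* Hill force-velocity scales   A_rel,0 = 0.1 + 0.4·r_fib,  B_rel,0 = 12·A_rel,0
* activation time constants    τ_ACT = 80 − 0.47·%FT ms, τ_DEACT = 90 − 0.56·%FT ms
                               (%FT = 100·r_fib; affine fiber-type interpolation,
                               a reconstruction of the standard formulation —
                               see docs/methods.md)

Angles are degrees in input records and configuration files and are converted
to radians exactly once, inside the trigonometric derivations.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .contraction import CurveShapeParams, default_curve_shapes
from .errors import ConfigurationError, DomainError

__all__ = [
    "MorphometryInput",
    "MuscleParameterSet",
    "compute_fmax",
    "compute_tendon_slack",
    "compute_mass",
    "hill_constants",
    "activation_time_constants",
    "derive_parameters",
    "reference_morphometry",
    "reference_parameters",
    "load_morphometry",
]

# affine fiber-type interpolation of the activation/deactivation time
# constants, in ms per %FT (reconstruction; reproduces 58.85/64.8 ms at 45 %FT
# and 80/90 ms, 33/34 ms at the slow/fast limits)
_TAU_ACT_MS = (80.0, -0.47)
_TAU_DEACT_MS = (90.0, -0.56)

#: Table-of-record morphometry of the study subject's M. gastrocnemius medialis
_REFERENCE_MORPH = dict(
    V=379.89e-6,        # m^3, MRI segmentation
    lMTU_rest=0.315,    # m, MTU length at neutral ankle angle
    lCE_opt=0.0574,     # m, optimal fiber length
    alpha=27.0,         # deg, pennation angle
    lever_arm=0.064,    # m, ankle moment arm
    sigma=0.25e6,       # Pa, maximum muscle stress
    rho=1059.7,         # kg/m^3, muscle tissue density
    r_fib=0.45,         # fast-twitch fiber ratio
)

#: Authoritative simulation mass (kg). The morphometric product V·ρ gives
#: 0.4026 kg; the study's own parameter table lists 0.3587 kg, which is kept
#: as the value of record for simulation (see docs/methods.md).
REFERENCE_MASS = 0.3587


@dataclass(frozen=True)
class MorphometryInput:
    """Subject geometry and tissue constants (SI units, angles in degrees)."""

    V: float
    lMTU_rest: float
    lCE_opt: float
    alpha: float
    lever_arm: float
    sigma: float
    rho: float
    r_fib: float

    def __post_init__(self):
        for name in ("V", "lMTU_rest", "lCE_opt", "lever_arm", "sigma", "rho"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be strictly positive")
        if not 0.0 <= self.r_fib <= 1.0:
            raise DomainError(f"r_fib={self.r_fib} outside [0, 1]")
        if not 0.0 <= self.alpha < 90.0:
            raise DomainError(f"alpha={self.alpha}° outside [0°, 90°)")
        if self.lCE_opt >= self.lMTU_rest:
            raise DomainError("optimal fiber length must be below the MTU rest length")


@dataclass(frozen=True)
class MuscleParameterSet:
    """Complete parameter vector of the contraction/activation/energetics model."""

    fmax: float          # N
    lce_opt: float       # m
    lsee_0: float        # m
    mass: float          # kg
    arel0: float
    brel0: float         # 1/s (per optimal length)
    tau_act: float       # s
    tau_deact: float     # s
    alpha: float         # deg
    lever_arm: float     # m
    lmtu_rest: float     # m
    r_fib: float
    curves: CurveShapeParams = field(default_factory=CurveShapeParams)

    def __post_init__(self):
        if self.fmax <= 0 or self.mass <= 0:
            raise DomainError("Fmax and mass must be strictly positive")
        if self.lsee_0 <= 0:
            raise DomainError("tendon slack length must be strictly positive")
        if self.tau_act > self.tau_deact:
            raise DomainError("activation must not be slower than deactivation")


def compute_fmax(sigma: float, V: float, lCE_opt: float, alpha: float) -> float:
    """Maximum isometric force (N): ``σ·V/l_CE_opt·cos(α)``, α in degrees."""
    if lCE_opt <= 0:
        raise DomainError("lCE_opt must be strictly positive")
    if sigma <= 0 or V <= 0:
        raise DomainError("sigma and V must be strictly positive")
    if not 0.0 <= alpha < 90.0:
        raise DomainError(f"alpha={alpha}° outside [0°, 90°)")
    return sigma * V / lCE_opt * math.cos(math.radians(alpha))


def compute_tendon_slack(lMTU_rest: float, lCE_opt: float) -> float:
    """Tendon slack length (m): MTU rest length minus optimal fiber length."""
    if lCE_opt >= lMTU_rest:
        raise DomainError("tendon slack must be positive (lCE_opt >= lMTU_rest)")
    return lMTU_rest - lCE_opt


def compute_mass(V: float, rho: float) -> float:
    """Muscle mass (kg): ``V·ρ``."""
    if V <= 0 or rho <= 0:
        raise DomainError("V and rho must be strictly positive")
    return V * rho


def hill_constants(r_fib: float) -> tuple[float, float]:
    """Nominal Hill force-velocity constants ``(A_rel,0, B_rel,0)``."""
    if not 0.0 <= r_fib <= 1.0:
        raise DomainError(f"r_fib={r_fib} outside [0, 1]")
    arel0 = 0.1 + 0.4 * r_fib
    return arel0, 12.0 * arel0


def activation_time_constants(r_fib: float) -> tuple[float, float]:
    """Activation/deactivation time constants (s) from the fiber composition."""
    if not 0.0 <= r_fib <= 1.0:
        raise DomainError(f"r_fib={r_fib} outside [0, 1]")
    pct_ft = 100.0 * r_fib
    tau_act = (_TAU_ACT_MS[0] + _TAU_ACT_MS[1] * pct_ft) / 1000.0
    tau_deact = (_TAU_DEACT_MS[0] + _TAU_DEACT_MS[1] * pct_ft) / 1000.0
    return tau_act, tau_deact


def derive_parameters(morph: MorphometryInput,
                      overrides: Mapping[str, float] | None = None,
                      curves: CurveShapeParams | None = None) -> MuscleParameterSet:
    """Derive the full parameter set from morphometry (deterministic and pure).

    ``overrides`` may replace any derived :class:`MuscleParameterSet` field
    (e.g. a mass of record that differs from ``V·ρ``); unknown keys raise
    :class:`ConfigurationError`.
    """
    arel0, brel0 = hill_constants(morph.r_fib)
    tau_act, tau_deact = activation_time_constants(morph.r_fib)
    values = dict(
        fmax=compute_fmax(morph.sigma, morph.V, morph.lCE_opt, morph.alpha),
        lce_opt=morph.lCE_opt,
        lsee_0=compute_tendon_slack(morph.lMTU_rest, morph.lCE_opt),
        mass=compute_mass(morph.V, morph.rho),
        arel0=arel0,
        brel0=brel0,
        tau_act=tau_act,
        tau_deact=tau_deact,
        alpha=morph.alpha,
        lever_arm=morph.lever_arm,
        lmtu_rest=morph.lMTU_rest,
        r_fib=morph.r_fib,
        curves=curves if curves is not None else default_curve_shapes(),
    )
    if overrides:
        allowed = {f.name for f in dataclasses.fields(MuscleParameterSet)}
        unknown = set(overrides) - allowed
        if unknown:
            raise ConfigurationError(f"unknown parameter overrides: {sorted(unknown)}")
        values.update(overrides)
    return MuscleParameterSet(**values)


def reference_morphometry() -> MorphometryInput:
    """The study subject's morphometric record."""
    return MorphometryInput(**_REFERENCE_MORPH)


def reference_parameters() -> MuscleParameterSet:
    """Parameter set of record: derived morphometry plus the tabulated mass."""
    return derive_parameters(reference_morphometry(),
                             overrides={"mass": REFERENCE_MASS})


def load_morphometry(path: str | Path) -> tuple[MorphometryInput, dict]:
    """Read a flat YAML/JSON morphometry document.

    Keys mirror :class:`MorphometryInput`; any additional key naming a
    :class:`MuscleParameterSet` field is collected as an override.  Unknown
    keys raise :class:`ConfigurationError`.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ConfigurationError(f"{path}: expected a flat key-value document")
    morph_keys = {f.name for f in dataclasses.fields(MorphometryInput)}
    param_keys = {f.name for f in dataclasses.fields(MuscleParameterSet)} - {"curves"}
    morph_kw, overrides = {}, {}
    for key, val in doc.items():
        if key in morph_keys:
            morph_kw[key] = float(val)
        elif key in param_keys:
            overrides[key] = float(val)
        else:
            raise ConfigurationError(f"{path}: unknown key {key!r}")
    missing = morph_keys - set(morph_kw)
    if missing:
        raise ConfigurationError(f"{path}: missing morphometry keys {sorted(missing)}")
    return MorphometryInput(**morph_kw), overrides
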