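"""Four-element Hill-type muscle-tendon-unit contraction dynamics.

The muscle-tendon unit (MTU) is modeled as a contractile element (CE, active
force-length-velocity behavior) in parallel with a passive elasticity (PEE),
both in series with the tendon, which is itself an elasticity (SEE) in
parallel with a damping element (SDE).  The single internal degree of freedom
is the fiber length ``l_CE``; its rate follows from the instantaneous force
balance

    F_CE(l_CE, l̇_CE, a) + F_PEE(l_CE) = F_SEE(l_MTU - l_CE) + F_SDE(l̇_MTU - l̇_CE)

which, for the hyperbolic force-velocity relation and a damping coefficient
linear in the elastic force, reduces to a quadratic equation in ``l̇_CE`` per
force-velocity branch.  Sign convention: ``l̇_CE < 0`` is fiber shortening.

Functional forms and shape constants follow the open-source macroscopic
muscle model family (see ``data/default_curves.yaml``); the subject-specific
scale parameters (Fmax, l_CE_opt, l_SEE_0, Hill constants) come from
:mod:`mtuenergy.parameters`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import TYPE_CHECKING, Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .activation import activation_derivative
from .defaults import load_default_constants
from .errors import ConfigurationError, ContractionSolveError, StateError

if TYPE_CHECKING:  # pragma: no cover
    from .parameters import MuscleParameterSet

__all__ = [
    "CurveShapeParams",
    "ForceBreakdown",
    "SolverConfig",
    "default_curve_shapes",
    "element_forces",
    "contraction_derivative",
    "initial_fiber_length",
    "simulate_mtu",
]

#: minimum admissible muscle activity (lower clamp of the activation state)
A_MIN = 0.001


@dataclass(frozen=True)
class CurveShapeParams:
    """Shape constants of the CE/PEE/SEE/SDE curves (dimensionless).

    Scale is provided by the subject-specific parameter set; these constants
    only fix the *shape* of each element's characteristic.
    """

    dw_des: float = 0.45
    nu_des: float = 1.5
    dw_asc: float = 0.45
    nu_asc: float = 3.0
    f_ecc: float = 1.5
    s_ecc: float = 2.0
    l_pee0: float = 0.95
    nu_pee: float = 2.5
    f_pee: float = 2.0
    du_see_nll: float = 0.0425
    du_see_l: float = 0.017
    rel_df_see0: float = 0.4
    d_sde: float = 0.3
    r_sde: float = 0.01


def default_curve_shapes() -> CurveShapeParams:
    """Curve shapes from the packaged versioned constants file."""
    return CurveShapeParams(**load_default_constants()["curves"])


@dataclass(frozen=True)
class ForceBreakdown:
    """Element forces (N) at one accepted state. ``F_MTU = F_SEE + F_SDE``."""

    F_CE: float
    F_PEE: float
    F_SEE: float
    F_SDE: float
    F_MTU: float

    @property
    def balance_residual(self) -> float:
        return self.F_CE + self.F_PEE - self.F_SEE - self.F_SDE


@dataclass(frozen=True)
class SolverConfig:
    """Integrator settings (variable-step, stiff-capable)."""

    rtol: float = 1e-4
    atol_lce: float = 1e-7  # m
    atol_a: float = 1e-6
    output_dt: float = 0.01  # s
    method: str = "LSODA"

    def __post_init__(self):
        if self.rtol <= 0 or self.atol_lce <= 0 or self.atol_a <= 0 or self.output_dt <= 0:
            raise ConfigurationError("solver tolerances and output step must be positive")


class _Engine:
    """Precompiled scalar-math evaluator for one parameter set (hot path)."""

    __slots__ = (
        "fmax", "lce_opt", "lsee0", "arel0", "brel0",
        "dw_des", "nu_des", "dw_asc", "nu_asc", "f_ecc", "s_ecc",
        "l_pee0_abs", "nu_pee", "k_pee",
        "l_see_nll", "nu_see", "k_see_nl", "k_see_l", "df_see0",
        "d_max", "r_sde",
    )

    def __init__(self, p: "MuscleParameterSet"):
        c = p.curves
        self.fmax = p.fmax
        self.lce_opt = p.lce_opt
        self.lsee0 = p.lsee_0
        self.arel0 = p.arel0
        self.brel0 = p.brel0
        self.dw_des = c.dw_des
        self.nu_des = c.nu_des
        self.dw_asc = c.dw_asc
        self.nu_asc = c.nu_asc
        self.f_ecc = c.f_ecc
        self.s_ecc = c.s_ecc
        self.l_pee0_abs = c.l_pee0 * p.lce_opt
        self.nu_pee = c.nu_pee
        self.k_pee = (
            c.f_pee * p.fmax / (p.lce_opt * (c.dw_des + 1.0 - c.l_pee0)) ** c.nu_pee
        )
        self.l_see_nll = (1.0 + c.du_see_nll) * p.lsee_0
        self.nu_see = c.du_see_nll / c.du_see_l
        self.df_see0 = c.rel_df_see0 * p.fmax
        self.k_see_nl = self.df_see0 / (c.du_see_nll * p.lsee_0) ** self.nu_see
        self.k_see_l = self.df_see0 / (c.du_see_l * p.lsee_0)
        self.d_max = c.d_sde * p.fmax * p.arel0 / (p.lce_opt * p.brel0)
        self.r_sde = c.r_sde

    # -- element characteristics ------------------------------------------

    def fisom(self, lce: float) -> float:
        """Normalized isometric force-length bell (1 at l_CE = l_CE_opt)."""
        rel = lce / self.lce_opt - 1.0
        if rel >= 0.0:
            return math.exp(-abs(rel / self.dw_des) ** self.nu_des)
        return math.exp(-abs(rel / self.dw_asc) ** self.nu_asc)

    def fpee(self, lce: float) -> float:
        if lce <= self.l_pee0_abs:
            return 0.0
        return self.k_pee * (lce - self.l_pee0_abs) ** self.nu_pee

    def fsee(self, lsee: float) -> float:
        if lsee <= self.lsee0:
            return 0.0
        if lsee < self.l_see_nll:
            return self.k_see_nl * (lsee - self.lsee0) ** self.nu_see
        return self.df_see0 + self.k_see_l * (lsee - self.l_see_nll)

    def hill_arel_brel(self, lce: float, a: float) -> tuple[float, float]:
        """Activity- and length-corrected concentric Hill constants."""
        la = 1.0 if lce < self.lce_opt else self.fisom(lce)
        arel = self.arel0 * la * 0.25 * (1.0 + 3.0 * a)
        brel = self.brel0 * (3.0 + 4.0 * a) / 7.0
        return arel, brel

    def fce_hyperbola(self, v: float, qf: float, arel: float, brel_l: float) -> float:
        """CE force on one Hill branch; ``qf = a*F_isom`` (normalized isometric)."""
        return self.fmax * ((qf + arel) / (1.0 - v / brel_l) - arel)

    def damping_coeff(self, f_elastic: float) -> float:
        """SDE coefficient, linear in the CE+PEE force (N s/m)."""
        return self.d_max * ((1.0 - self.r_sde) * f_elastic / self.fmax + self.r_sde)

    # -- fiber velocity from the force balance ----------------------------

    def _branch_roots(self, arel: float, brel_l: float, qf: float,
                      fp: float, fs: float, vmtu: float) -> list[float]:
        """Real roots of the force balance on one Hill branch.

        The residual multiplied by the hyperbola denominator ``(1 - v/(B l))``
        is exactly quadratic in ``v``; its coefficients are recovered from
        three exact samples, which avoids error-prone hand algebra.
        """
        h = 0.5 * abs(brel_l)

        def r(v: float) -> float:
            den = 1.0 - v / brel_l
            fce = self.fmax * ((qf + arel) / den - arel)
            g = fce + fp - fs - self.damping_coeff(fce + fp) * (vmtu - v)
            return den * g

        r0, rp, rm = r(0.0), r(h), r(-h)
        a2 = (rp + rm - 2.0 * r0) / (2.0 * h * h)
        a1 = (rp - rm) / (2.0 * h)
        a0 = r0
        scale = max(abs(a0), abs(a1) * h, abs(a2) * h * h, 1e-300)
        if abs(a2) * h * h < 1e-12 * scale:  # effectively linear
            if abs(a1) * h < 1e-12 * scale:
                return []
            roots = [-a0 / a1]
        else:
            disc = a1 * a1 - 4.0 * a2 * a0
            if disc < 0.0:
                return []
            sq = math.sqrt(disc)
            roots = [(-a1 - sq) / (2.0 * a2), (-a1 + sq) / (2.0 * a2)]
        # keep roots on the admissible side of the hyperbola asymptote and
        # with a non-negative damping coefficient (roots in the negative-
        # damping regime solve the algebra but not the physics)
        out = []
        for v in roots:
            den = 1.0 - v / brel_l
            if den <= 1e-9:
                continue
            fce = self.fmax * ((qf + arel) / den - arel)
            if self.damping_coeff(fce + fp) >= 0.0:
                out.append(v)
        return out

    def fiber_velocity(self, lce: float, lmtu: float, vmtu: float, a: float) -> float:
        """Solve the CE/PEE vs SEE/SDE force balance for ``l̇_CE`` (m/s)."""
        lsee = lmtu - lce
        if lsee <= 0.0:
            raise StateError(f"fiber longer than MTU (l_CE={lce:.4f}, l_MTU={lmtu:.4f})")
        a = min(max(a, A_MIN), 1.0)
        fis = self.fisom(lce)
        # floor keeps the hyperbola scales finite at extreme trial states of
        # the integrator (the bell underflows far from optimal length)
        qf = max(a * fis, 1e-12)
        fp = self.fpee(lce)
        fs = self.fsee(lsee)
        arel, brel = self.hill_arel_brel(lce, a)
        brel_l = brel * self.lce_opt  # concentric velocity scale (> 0)
        tol = 1e-12 * brel_l

        # concentric branch (shortening, v <= 0); ties at zero net force break
        # toward this branch
        conc = [v for v in self._branch_roots(arel, brel_l, qf, fp, fs, vmtu)
                if v <= tol]
        if conc:
            return min(conc, key=abs)

        # eccentric branch (lengthening, v >= 0): hyperbola with asymptote at
        # f_ecc times the isometric force and s_ecc times the concentric slope
        # at v = 0
        arel_e = -self.f_ecc * qf
        brel_e = brel * qf * (1.0 - self.f_ecc) / (self.s_ecc * (qf + arel))
        brel_el = brel_e * self.lce_opt  # < 0
        ecc = [v for v in self._branch_roots(arel_e, brel_el, qf, fp, fs, vmtu)
               if v >= -tol]
        if ecc:
            return min(ecc, key=abs)

        # guarded numeric fallback on the exact residual
        return self._fallback_root(lce, vmtu, a, qf, fp, fs, arel, brel_l,
                                   arel_e, brel_el)

    def _fallback_root(self, lce, vmtu, a, qf, fp, fs, arel, brel_l,
                       arel_e, brel_el) -> float:
        def g(v: float) -> float:
            if v <= 0.0:
                fce = self.fce_hyperbola(v, qf, arel, brel_l)
            else:
                fce = self.fce_hyperbola(v, qf, arel_e, brel_el)
            return fce + fp - fs - self.damping_coeff(fce + fp) * (vmtu - v)

        lo = -0.999 * brel_l * (qf + arel) / max(arel, 1e-12)  # past unloaded speed
        lo = -abs(lo)
        hi = abs(vmtu) + brel_l
        for _ in range(60):
            if g(lo) * g(hi) <= 0.0:
                return brentq(g, lo, hi, xtol=1e-12, rtol=1e-12)
            lo *= 1.5
            hi *= 1.5
        raise ContractionSolveError(
            "no admissible fiber-velocity root",
            {"l_CE": lce, "l̇_MTU": vmtu, "a": a, "F_SEE": fs, "F_PEE": fp},
        )


@lru_cache(maxsize=32)
def _engine_cached(p: "MuscleParameterSet") -> _Engine:
    return _Engine(p)


def _engine(p: "MuscleParameterSet") -> _Engine:
    try:
        return _engine_cached(p)
    except TypeError:  # unhashable ad-hoc parameter object
        return _Engine(p)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def element_forces(lce: float, lmtu: float, lce_dot: float, lmtu_dot: float,
                   a: float, params: "MuscleParameterSet") -> ForceBreakdown:
    """Evaluate every element's force at the given state (N)."""
    e = _engine(params)
    lsee = lmtu - lce
    if lsee <= 0.0:
        raise StateError(f"fiber longer than MTU (l_CE={lce:.4f}, l_MTU={lmtu:.4f})")
    a = min(max(a, A_MIN), 1.0)
    fis = e.fisom(lce)
    qf = max(a * fis, 1e-12)
    arel, brel = e.hill_arel_brel(lce, a)
    brel_l = brel * e.lce_opt
    if lce_dot <= 0.0:
        f_ce = e.fce_hyperbola(lce_dot, qf, arel, brel_l)
    else:
        arel_e = -e.f_ecc * qf
        brel_el = brel * qf * (1.0 - e.f_ecc) / (e.s_ecc * (qf + arel)) * e.lce_opt
        f_ce = e.fce_hyperbola(lce_dot, qf, arel_e, brel_el)
    f_pee = e.fpee(lce)
    f_see = e.fsee(lsee)
    f_sde = e.damping_coeff(f_ce + f_pee) * (lmtu_dot - lce_dot)
    return ForceBreakdown(f_ce, f_pee, f_see, f_sde, f_see + f_sde)


def contraction_derivative(lce: float, lmtu: float, lmtu_dot: float, a: float,
                           params: "MuscleParameterSet") -> float:
    """Fiber velocity ``l̇_CE`` (m/s, negative = shortening) from the force balance."""
    return _engine(params).fiber_velocity(lce, lmtu, lmtu_dot, a)


def initial_fiber_length(lmtu_init: float, a_init: float,
                         params: "MuscleParameterSet") -> float:
    """Fiber length of the static force equilibrium at rest.

    With all velocities zero the balance reduces to
    ``a·F_isom(l_CE)·Fmax + F_PEE(l_CE) = F_SEE(l_MTU - l_CE)``; the root is
    bracketed on the side where the tendon is taut and refined to a residual
    below ``1e-6·Fmax``.
    """
    e = _engine(params)
    if lmtu_init <= params.lsee_0:
        raise ConfigurationError(
            f"initial MTU length {lmtu_init} not above tendon slack length {params.lsee_0}"
        )
    a = min(max(a_init, A_MIN), 1.0)

    def residual(lce: float) -> float:
        return a * e.fisom(lce) * e.fmax + e.fpee(lce) - e.fsee(lmtu_init - lce)

    hi = min(lmtu_init - params.lsee_0, lmtu_init * 0.999)
    if residual(hi) < 0.0:  # extremely stiff configuration; widen upward
        raise ConfigurationError("no bracketing interval: residual negative at slack point")
    lo = hi
    step = 0.05 * params.lce_opt
    while residual(lo) > 0.0:
        lo -= step
        if lo <= 0.05 * params.lce_opt:
            raise ConfigurationError("no bracketing interval for the static equilibrium")
    root = brentq(residual, lo, lo + step, xtol=1e-12, rtol=8.9e-16)
    return float(root)


@dataclass
class SimulationTrajectory:
    """State, force and (optionally appended) energy time courses."""

    data: pd.DataFrame

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.10g")


def _interp1(t: np.ndarray, y: np.ndarray) -> Callable[[float], float]:
    def f(x: float) -> float:
        return float(np.interp(x, t, y))
    return f


def simulate_mtu(kin, stim, params: "MuscleParameterSet",
                 solver_cfg: SolverConfig | None = None,
                 t_span: tuple[float, float] | None = None,
                 a_init: float | None = None) -> SimulationTrajectory:
    """Integrate the coupled contraction + activation dynamics.

    Parameters
    ----------
    kin : KinematicsSeries
        Time courses of ``l_MTU`` and ``l̇_MTU`` (linearly interpolated).
    stim : StimulationSeries
        Neuronal stimulation ``u(t)`` in [0, 1] (linearly interpolated).
    params : MuscleParameterSet
    solver_cfg : SolverConfig, optional
    t_span : (t0, t1), optional
        Defaults to the overlap of the input series.

    Initial conditions follow the static-equilibrium convention:
    ``a(0) = u(0)`` (clamped to the admissible activity range) and ``l_CE(0)``
    from :func:`initial_fiber_length`.
    """
    cfg = solver_cfg or SolverConfig()
    e = _engine(params)
    t_kin = np.asarray(kin.t, dtype=float)
    t_u = np.asarray(stim.t, dtype=float)
    if t_kin.size == 0 or t_u.size == 0:
        raise ConfigurationError("empty input series")
    t0 = max(t_kin[0], t_u[0]) if t_span is None else t_span[0]
    t1 = min(t_kin[-1], t_u[-1]) if t_span is None else t_span[1]
    if not t1 > t0:
        raise ConfigurationError("kinematics and stimulation have no common time span")

    lmtu_arr = np.asarray(kin.lmtu, dtype=float)
    vmtu_arr = np.asarray(kin.lmtu_dot, dtype=float)
    u_arr = np.clip(np.asarray(stim.u, dtype=float), 0.0, 1.0)
    lmtu_f = _interp1(t_kin, lmtu_arr)
    vmtu_f = _interp1(t_kin, vmtu_arr)
    u_f = _interp1(t_u, u_arr)

    tau_act, tau_deact = params.tau_act, params.tau_deact
    a0 = min(max(u_f(t0) if a_init is None else a_init, A_MIN), 1.0)
    lce0 = initial_fiber_length(lmtu_f(t0), a0, params)

    def rhs(t: float, y):
        lce, a = y[0], min(max(y[1], A_MIN), 1.0)
        lmtu = lmtu_f(t)
        if lmtu - lce <= 1e-6:
            # out-of-domain trial state of the integrator: steer back with a
            # finite restoring velocity instead of failing the step
            dlce = -1e3 * (lce - (lmtu - 1e-4))
        else:
            dlce = e.fiber_velocity(lce, lmtu, vmtu_f(t), a)
        da = activation_derivative(u_f(t), a, tau_act, tau_deact)
        return (dlce, da)

    t_eval = np.arange(t0, t1 + 0.5 * cfg.output_dt, cfg.output_dt)
    t_eval = t_eval[t_eval <= t1]
    sol = solve_ivp(rhs, (t0, t1), (lce0, a0), method=cfg.method,
                    rtol=cfg.rtol, atol=(cfg.atol_lce, cfg.atol_a),
                    t_eval=t_eval, dense_output=False)
    if not sol.success:
        raise ContractionSolveError(
            f"integration failed: {sol.message}",
            {"t_last": float(sol.t[-1]) if sol.t.size else t0},
        )

    t = sol.t
    lce = sol.y[0]
    act = np.clip(sol.y[1], A_MIN, 1.0)
    n = t.size
    lmtu = np.interp(t, t_kin, lmtu_arr)
    vmtu = np.interp(t, t_kin, vmtu_arr)
    u = np.interp(t, t_u, u_arr)
    lce_dot = np.empty(n)
    f_ce = np.empty(n)
    f_pee = np.empty(n)
    f_see = np.empty(n)
    f_sde = np.empty(n)
    for i in range(n):
        v = e.fiber_velocity(lce[i], lmtu[i], vmtu[i], act[i])
        fb = element_forces(lce[i], lmtu[i], v, vmtu[i], act[i], params)
        lce_dot[i] = v
        f_ce[i] = fb.F_CE
        f_pee[i] = fb.F_PEE
        f_see[i] = fb.F_SEE
        f_sde[i] = fb.F_SDE
    df = pd.DataFrame({
        "t": t, "lmtu": lmtu, "lmtu_dot": vmtu, "u": u, "a": act,
        "lce": lce, "lce_dot": lce_dot,
        "F_CE": f_ce, "F_PEE": f_pee, "F_SEE": f_see, "F_SDE": f_sde,
        "F_MTU": f_see + f_sde,
    })
    return SimulationTrajectory(df)
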