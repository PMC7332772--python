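"""First-order activation dynamics.

Maps neuronal stimulation ``u(t)`` (normalized, rectified EMG) to muscle
activity ``a(t)`` through

    ȧ = (u - a) · ((1/τ_ACT - 1/τ_DEACT)·u + 1/τ_DEACT)

i.e. a first-order relaxation whose effective rate blends the activation and
deactivation time constants with the stimulation level.  ``a`` is clamped to
[0.001, 1]: the lower bound prevents singular force terms downstream, the
upper bound is full activity.  Between samples ``u`` is linearly
interpolated.
"""
from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConfigurationError

__all__ = ["activation_derivative", "integrate_activation", "A_MIN"]

A_MIN = 0.001


def activation_derivative(u: float, a: float, tau_act: float, tau_deact: float) -> float:
    """Rate of change of muscle activity (1/s).

    Fixed point at ``a = u``; for constant ``u`` the dynamics is linear in
    ``a`` with effective time constant ``1 / ((1/τ_ACT - 1/τ_DEACT)·u + 1/τ_DEACT)``.
    """
    if tau_act <= 0 or tau_deact <= 0:
        raise ConfigurationError("time constants must be positive")
    rate = (1.0 / tau_act - 1.0 / tau_deact) * u + 1.0 / tau_deact
    return (u - a) * rate


def integrate_activation(t, u, a0: float, tau_act: float, tau_deact: float,
                         rtol: float = 1e-8, atol: float = 1e-10):
    """Integrate the activation dynamics over a sampled stimulation series.

    Parameters
    ----------
    t, u : array-like
        Strictly increasing sample times (s) and stimulation in [0, 1].
    a0 : float
        Initial activity in [A_MIN, 1].

    Returns
    -------
    ndarray
        ``a(t)`` on the input grid, clamped to [A_MIN, 1].
    """
    t = np.asarray(t, dtype=float)
    u = np.asarray(u, dtype=float)
    if t.size == 0:
        raise ConfigurationError("empty stimulation series")
    if t.size != u.size:
        raise ConfigurationError("time and stimulation arrays differ in length")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ConfigurationError("time grid must be strictly increasing")
    if not (A_MIN <= a0 <= 1.0):
        raise ConfigurationError(f"a0={a0} outside [{A_MIN}, 1]")
    if t.size == 1:
        return np.array([a0])

    def rhs(ti, y):
        ui = float(np.interp(ti, t, u))
        ai = min(max(y[0], A_MIN), 1.0)
        return (activation_derivative(ui, ai, tau_act, tau_deact),)

    sol = solve_ivp(rhs, (t[0], t[-1]), (a0,), method="LSODA",
                    rtol=rtol, atol=atol, t_eval=t)
    if not sol.success:  # pragma: no cover - smooth linear ODE
        raise RuntimeError(f"activation integration failed: {sol.message}")
    return np.clip(sol.y[0], A_MIN, 1.0)
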