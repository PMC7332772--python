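"""Metabolic energy-rate accounting along contraction trajectories.

The total mass-specific metabolic rate of the muscle is decomposed as

    Ė = ḣ_AM + ḣ_SL + ẇ_CE        [W/kg = J kg⁻¹ s⁻¹]

with

* ``ḣ_AM`` — activation + maintenance heat: a fiber-type dependent nominal
  fully-active rate (1.28·%FT + 25 W/kg) scaled by the effective activation
  ``A^0.6`` and, above optimal fiber length, by the force-length factor;
* ``ḣ_SL`` — shortening/lengthening heat: proportional to the normalized
  fiber velocity with distinct slow/fast-twitch shortening coefficients
  (tied to the slow/fast maximum shortening velocities) and a lengthening
  coefficient; activation enters squared for shortening and linearly for
  lengthening;
* ``ẇ_CE`` — mechanical work rate of the fibers, ``−F_CE·l̇_CE/M`` (positive
  during shortening; ``l̇_CE < 0`` is shortening).

The effective activation blends stimulation and activity:
``A = u`` while activating (u ≥ a) and ``A = (u+a)/2`` while deactivating.
The total rate is clamped at ≥ 0 (this accounting cannot net-absorb chemical
energy); the components are reported unclamped so the decomposition stays
inspectable.  All coefficients live in the packaged constants file and are
reconstructions of the published energy model for mixed fiber-type muscle.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .contraction import _engine
from .defaults import load_default_constants

if TYPE_CHECKING:  # pragma: no cover
    from .parameters import MuscleParameterSet

__all__ = [
    "EnergeticsConstants",
    "EnergyRateBreakdown",
    "default_energetics_constants",
    "effective_activation",
    "heat_activation_maintenance",
    "heat_shortening_lengthening",
    "mechanical_work_rate",
    "total_energy_rate",
    "evaluate_trajectory",
]

A_MIN = 0.001


@dataclass(frozen=True)
class EnergeticsConstants:
    am_rate_base: float = 25.0
    am_rate_ft_slope: float = 1.28
    exp_heat_a: float = 0.6
    exp_short_a: float = 2.0
    exp_len_a: float = 1.0
    vmax_ft: float = 12.0
    vmax_st_ratio: float = 2.5
    alpha_s_st_num: float = 100.0
    alpha_s_ft_num: float = 153.0
    alpha_len_factor: float = 4.0

    @property
    def vmax_st(self) -> float:
        return self.vmax_ft / self.vmax_st_ratio

    @property
    def alpha_s_st(self) -> float:
        """Slow-twitch shortening heat coefficient (W/kg per l_opt/s)."""
        return self.alpha_s_st_num / self.vmax_st

    @property
    def alpha_s_ft(self) -> float:
        return self.alpha_s_ft_num / self.vmax_ft

    @property
    def alpha_len(self) -> float:
        return self.alpha_len_factor * self.alpha_s_st


@lru_cache(maxsize=1)
def default_energetics_constants() -> EnergeticsConstants:
    return EnergeticsConstants(**load_default_constants()["energetics"])


@dataclass(frozen=True)
class EnergyRateBreakdown:
    """Mass-specific rates (W/kg); ``E_dot`` is the clamped total."""

    h_AM: float
    h_SL: float
    w_CE: float
    E_dot: float


def effective_activation(u: float, a: float) -> float:
    """Blend of stimulation and activity driving the heat rates."""
    A = u if u >= a else 0.5 * (u + a)
    return min(max(A, A_MIN), 1.0)


def _am_nominal(r_fib: float, const: EnergeticsConstants) -> float:
    return const.am_rate_ft_slope * 100.0 * r_fib + const.am_rate_base


def heat_activation_maintenance(lce: float, u: float, a: float,
                                params: "MuscleParameterSet",
                                const: EnergeticsConstants | None = None) -> float:
    """Activation + maintenance heat rate (W/kg, non-negative)."""
    const = const or default_energetics_constants()
    A = effective_activation(u, a)
    rate = _am_nominal(params.r_fib, const) * A ** const.exp_heat_a
    if lce > params.lce_opt:
        fis = _engine(params).fisom(lce)
        rate *= 0.4 + 0.6 * fis
    return rate


def heat_shortening_lengthening(lce_dot: float, lce: float, u: float, a: float,
                                params: "MuscleParameterSet",
                                const: EnergeticsConstants | None = None) -> float:
    """Shortening/lengthening heat rate (W/kg, non-negative, 0 at l̇_CE = 0)."""
    const = const or default_energetics_constants()
    A = effective_activation(u, a)
    v_norm = lce_dot / params.lce_opt  # 1/s, negative = shortening
    if v_norm < 0.0:
        alpha = (const.alpha_s_st * (1.0 - params.r_fib)
                 + const.alpha_s_ft * params.r_fib)
        rate = -alpha * v_norm * A ** const.exp_short_a
    else:
        rate = const.alpha_len * v_norm * A ** const.exp_len_a
    if lce > params.lce_opt:
        rate *= _engine(params).fisom(lce)
    return rate


def mechanical_work_rate(f_ce: float, lce_dot: float, mass: float) -> float:
    """Mass-specific fiber work rate (W/kg): ``−F_CE·l̇_CE/M``."""
    if mass <= 0:
        raise ValueError("mass must be strictly positive")
    return -f_ce * lce_dot / mass


def total_energy_rate(lce: float, lce_dot: float, u: float, a: float, f_ce: float,
                      params: "MuscleParameterSet",
                      const: EnergeticsConstants | None = None) -> EnergyRateBreakdown:
    """All three components plus the clamped total at one state."""
    h_am = heat_activation_maintenance(lce, u, a, params, const)
    h_sl = heat_shortening_lengthening(lce_dot, lce, u, a, params, const)
    w_ce = mechanical_work_rate(f_ce, lce_dot, params.mass)
    return EnergyRateBreakdown(h_am, h_sl, w_ce, max(h_am + h_sl + w_ce, 0.0))


def evaluate_trajectory(traj: pd.DataFrame, params: "MuscleParameterSet",
                        const: EnergeticsConstants | None = None) -> pd.DataFrame:
    """Append energy-rate columns (h_AM, h_SL, w_CE, E_dot, E_cum) to a trajectory.

    ``E_cum`` (J/kg) is the trapezoidal integral of the clamped total rate
    over the trajectory grid, zero at the first sample.
    """
    const = const or default_energetics_constants()
    e = _engine(params)
    lce = traj["lce"].to_numpy()
    lce_dot = traj["lce_dot"].to_numpy()
    u = traj["u"].to_numpy()
    a = traj["a"].to_numpy()
    f_ce = traj["F_CE"].to_numpy()

    A = np.where(u >= a, u, 0.5 * (u + a))
    A = np.clip(A, A_MIN, 1.0)
    fis = np.array([e.fisom(x) for x in lce])
    above = lce > params.lce_opt

    h_am = _am_nominal(params.r_fib, const) * A ** const.exp_heat_a
    h_am = np.where(above, h_am * (0.4 + 0.6 * fis), h_am)

    v_norm = lce_dot / params.lce_opt
    alpha_s = (const.alpha_s_st * (1.0 - params.r_fib)
               + const.alpha_s_ft * params.r_fib)
    h_sl = np.where(v_norm < 0.0,
                    -alpha_s * v_norm * A ** const.exp_short_a,
                    const.alpha_len * v_norm * A ** const.exp_len_a)
    h_sl = np.where(above, h_sl * fis, h_sl)

    w_ce = -f_ce * lce_dot / params.mass
    e_dot = np.maximum(h_am + h_sl + w_ce, 0.0)
    t = traj["t"].to_numpy()
    e_cum = cumulative_trapezoid(e_dot, t, initial=0.0)

    out = traj.copy()
    out["h_AM"] = h_am
    out["h_SL"] = h_sl
    out["w_CE"] = w_ce
    out["E_dot"] = e_dot
    out["E_cum"] = e_cum
    return out
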