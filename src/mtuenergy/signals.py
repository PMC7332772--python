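"""Convert recorded pedal angle and surface EMG into model inputs.

The pedal/ankle angle φ (degrees; 0° = foot sole perpendicular to the shank,
positive = plantarflexion) maps to MTU length through a constant moment arm:

    l_MTU(φ) = l_MTU(0°) − r·φ_rad

so plantarflexion shortens the gastrocnemius MTU.  The angle record is fitted
with tenth-order polynomials (piecewise, on time rescaled to [−1, 1] per
segment for conditioning) whose analytic derivative provides a smooth
``l̇_MTU(t)``.  The stimulation input ``u(t)`` is the full-wave rectified EMG
normalized to the maximum-voluntary-contraction reference; by default it is
fed unsmoothed, with an optional moving-RMS envelope for noisy inputs.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError

__all__ = [
    "AngleSeries",
    "KinematicsSeries",
    "StimulationSeries",
    "angle_to_mtu_length",
    "AnglePolynomial",
    "fit_angle_polynomial",
    "kinematics_from_angle",
    "process_emg",
    "read_two_column",
]


@dataclass
class AngleSeries:
    """Pedal/ankle angle record: times (s) and angles (degrees)."""

    t: np.ndarray
    phi: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.t.size != self.phi.size:
            raise ConfigurationError("angle series arrays differ in length")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ConfigurationError("angle time grid must be strictly increasing")
        if self.phi.size and (self.phi.min() < -5.0 or self.phi.max() > 40.0):
            raise DomainError("pedal angle outside the [-5°, 40°] sanity band")


@dataclass
class KinematicsSeries:
    """MTU length and velocity time courses (m, m/s)."""

    t: np.ndarray
    lmtu: np.ndarray
    lmtu_dot: np.ndarray


@dataclass
class StimulationSeries:
    """Normalized neuronal stimulation u(t) in [0, 1]."""

    t: np.ndarray
    u: np.ndarray


def angle_to_mtu_length(phi_deg, lever_arm: float, lmtu_rest: float,
                        lsee_0: float | None = None):
    """Map pedal angle (degrees) to MTU length (m); affine, decreasing in φ."""
    if lever_arm <= 0:
        raise DomainError("lever arm must be strictly positive")
    lmtu = lmtu_rest - lever_arm * np.radians(np.asarray(phi_deg, dtype=float))
    if lsee_0 is not None and np.any(lmtu <= lsee_0):
        raise DomainError("MTU length at or below the tendon slack length")
    return lmtu


@dataclass
class AnglePolynomial:
    """Piecewise polynomial fit of an angle record with analytic derivative.

    Each contiguous time segment holds one Chebyshev-scaled polynomial
    (numpy ``Polynomial.fit``); ``rms_error`` is the fit residual against the
    samples, in degrees.
    """

    edges: np.ndarray                 # segment boundaries, len = n_segments+1
    polys: list = field(default_factory=list)
    rms_error: float = 0.0

    def _segment(self, t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.edges, t, side="right") - 1
        return np.clip(idx, 0, len(self.polys) - 1)

    def phi(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = self._segment(t)
        out = np.empty_like(t)
        for k in np.unique(idx):
            m = idx == k
            out[m] = self.polys[k](t[m])
        return out

    def phi_dot(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = self._segment(t)
        out = np.empty_like(t)
        for k in np.unique(idx):
            m = idx == k
            out[m] = self.polys[k].deriv()(t[m])
        return out


def fit_angle_polynomial(series: AngleSeries, order: int = 10,
                         segment_duration: float | None = None) -> AnglePolynomial:
    """Fit tenth-order polynomials to the angle record, piecewise in time.

    A single global polynomial of modest order cannot track minutes of
    periodic pedaling, so long records are split into contiguous segments
    (default 1.25 s, one pedaling cycle at the study cadence; records spanning
    ≤ 2 s are fitted as a single segment).  Within each segment the fit is
    performed on time rescaled to [−1, 1], which keeps the tenth-order
    Vandermonde system well conditioned; the derivative is the analytic
    polynomial derivative mapped back to seconds.
    """
    t, phi = series.t, series.phi
    if t.size < order + 1:
        raise ConfigurationError(
            f"need at least {order + 1} samples for an order-{order} fit")
    span = t[-1] - t[0]
    if segment_duration is None:
        segment_duration = span if span <= 2.0 else 1.25
    n_seg = max(1, int(math.ceil(span / segment_duration - 1e-9)))
    edges = np.linspace(t[0], t[-1], n_seg + 1)

    polys = []
    sq_sum, n_pts = 0.0, 0
    for k in range(n_seg):
        m = (t >= edges[k]) & (t <= edges[k + 1])
        tk, pk = t[m], phi[m]
        if tk.size < order + 1:
            raise ConfigurationError(
                f"segment {k} has {tk.size} samples; lower the order or "
                "enlarge segment_duration")
        with warnings.catch_warnings():
            warnings.simplefilter("error", np.exceptions.RankWarning)
            try:
                poly = np.polynomial.Polynomial.fit(tk, pk, deg=order)
            except np.exceptions.RankWarning as exc:
                raise ConfigurationError(
                    f"rank-deficient fit in segment {k}; lower the order") from exc
        polys.append(poly)
        resid = poly(tk) - pk
        sq_sum += float(np.dot(resid, resid))
        n_pts += tk.size
    return AnglePolynomial(edges=edges, polys=polys,
                           rms_error=math.sqrt(sq_sum / n_pts))


def kinematics_from_angle(series: AngleSeries, lever_arm: float, lmtu_rest: float,
                          order: int = 10, segment_duration: float | None = None,
                          output_dt: float = 0.005,
                          lsee_0: float | None = None) -> KinematicsSeries:
    """Angle record → smooth (l_MTU, l̇_MTU) on a regular grid.

    Composes the piecewise polynomial fit with the constant-moment-arm
    mapping; ``l̇_MTU = −r·φ̇_rad``.
    """
    fit = fit_angle_polynomial(series, order=order, segment_duration=segment_duration)
    t = np.arange(series.t[0], series.t[-1] + 0.5 * output_dt, output_dt)
    t = t[t <= series.t[-1]]
    phi = fit.phi(t)
    lmtu = angle_to_mtu_length(phi, lever_arm, lmtu_rest, lsee_0=lsee_0)
    lmtu_dot = -lever_arm * np.radians(fit.phi_dot(t))
    return KinematicsSeries(t=t, lmtu=lmtu, lmtu_dot=lmtu_dot)


def process_emg(t, raw, mvc_reference: float,
                smooth_window: float | None = None,
                out_grid=None) -> StimulationSeries:
    """Rectify, MVC-normalize and (optionally) envelope a raw EMG record.

    Parameters
    ----------
    t, raw : array-like
        Sample times (s) and raw (or already rectified) EMG amplitudes.
    mvc_reference : float
        Maximum-voluntary-contraction reference amplitude (> 0).
    smooth_window : float, optional
        Moving-RMS envelope window in seconds; default None = no smoothing
        (the rectified signal is fed directly as stimulation).
    out_grid : array-like, optional
        Resample the result onto this time grid (linear interpolation).

    Values above 1 after normalization are clipped; the clip fraction is
    reported as a warning.
    """
    if mvc_reference <= 0:
        raise DomainError("mvc_reference must be strictly positive")
    t = np.asarray(t, dtype=float)
    raw = np.asarray(raw, dtype=float)
    if t.size != raw.size or t.size == 0:
        raise ConfigurationError("EMG record empty or arrays differ in length")
    u = np.abs(raw) / mvc_reference
    if smooth_window is not None:
        if smooth_window <= 0:
            raise ConfigurationError("smooth_window must be positive")
        dt = float(np.median(np.diff(t))) if t.size > 1 else smooth_window
        n = max(1, int(round(smooth_window / dt)))
        kernel = np.ones(n) / n
        u = np.sqrt(np.convolve(u * u, kernel, mode="same"))
    n_clip = int(np.count_nonzero(u > 1.0))
    if n_clip:
        warnings.warn(f"clipped {n_clip}/{u.size} EMG samples above the MVC reference "
                      f"({100.0 * n_clip / u.size:.2f}%)")
    u = np.clip(u, 0.0, 1.0)
    if out_grid is not None:
        out_grid = np.asarray(out_grid, dtype=float)
        u = np.interp(out_grid, t, u)
        t = out_grid
    return StimulationSeries(t=t, u=u)


def read_two_column(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a delimited text file with two columns (t, value).

    Header optional, '.' decimal point, '#' comment lines; the delimiter is
    sniffed (comma, tab or whitespace).
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 2:
        raise ConfigurationError(f"{path}: expected two columns")
    first = df.columns[0]
    try:  # headerless file: the "column names" are the first data row
        float(first)
        df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
    except ValueError:
        pass
    return (df.iloc[:, 0].to_numpy(dtype=float),
            df.iloc[:, 1].to_numpy(dtype=float))
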