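"""Pendant-drop tensiometry analysis.

Surface pressure Pi = IFT_o/w - IFT, plateau (steady-state) detection by
a trailing-window slope criterion, the adsorption cooperativity factor

    alpha = (Pi_sim - Pi_particle) / Pi_enzyme,

and the detachment energy of a spherical particle from the liquid-liquid
interface, E = pi r^2 IFT_o/w (1 - sign*cos theta)^2.

alpha = 1 means enzyme and particles adsorb independently (their surface
pressures add); alpha < 1 means the particles partially block or
restructure the interface against enzyme adsorption.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator

from .datatypes import (
    CooperativityResult,
    DesorptionEnergyResult,
    IFTTrace,
    SurfacePressureResult,
)
from .presets import PLATEAU_SLOPE_MN_PER_M_PER_MIN, PLATEAU_WINDOW_S

__all__ = [
    "surface_pressure",
    "SteadyStateDetector",
    "steady_state",
    "cooperativity",
    "desorption_energy",
]


def surface_pressure(ift, ift_ref):
    """Surface pressure Pi = ift_ref - ift, in mN/m.

    Negative values are reported as-is (pressures can fluctuate around
    zero when nothing adsorbs); vectorised over ``ift``.
    """
    ift = np.asarray(ift, dtype=float)
    ift_ref = float(ift_ref)
    if not np.all(np.isfinite(ift)) or not np.isfinite(ift_ref):
        raise ValueError("IFT values must be finite")
    pi = ift_ref - ift
    return float(pi) if pi.ndim == 0 else pi


class SteadyStateDetector(BaseEstimator):
    """Plateau detection on an IFT trace by trailing-window slope.

    The plateau criterion is the averaged decline over the final
    ``window_s`` seconds (default 3 min): the least-squares slope of IFT
    against time over that window must be below ``slope_threshold``
    (mN/m per minute, default 0.005) in absolute value.  A least-squares
    slope is used rather than an endpoint difference because it is robust
    to measurement noise.

    Fitted attributes
    -----------------
    plateau_slope_ : float
        Trailing-window slope in mN/m per minute.
    plateau_ift_ : float
        Mean IFT over the trailing window, mN/m.
    plateau_reached_ : bool
        ``|plateau_slope_| < slope_threshold``.
    pi_ : float
        Surface pressure against the trace's reference IFT, mN/m.
    result_ : SurfacePressureResult
    """

    def __init__(
        self,
        window_s: float = PLATEAU_WINDOW_S,
        slope_threshold: float = PLATEAU_SLOPE_MN_PER_M_PER_MIN,
    ):
        self.window_s = window_s
        self.slope_threshold = slope_threshold

    def fit(self, trace: IFTTrace) -> "SteadyStateDetector":
        if self.window_s <= 0 or self.slope_threshold <= 0:
            raise ValueError("window_s and slope_threshold must be positive")
        if trace.duration_s < self.window_s:
            raise ValueError(
                f"insufficient duration: trace spans {trace.duration_s:.1f} s "
                f"< window of {self.window_s:.1f} s"
            )
        t_end = trace.time_s[-1]
        mask = trace.time_s >= t_end - self.window_s
        t_win = trace.time_s[mask]
        ift_win = trace.ift_mN_per_m[mask]
        slope_per_s = np.polyfit(t_win, ift_win, 1)[0]
        self.plateau_slope_ = float(slope_per_s * 60.0)
        self.plateau_ift_ = float(np.mean(ift_win))
        # strict |slope| < threshold; a slope at the threshold up to float
        # jitter in the fit does not count as a plateau
        self.plateau_reached_ = bool(
            self.slope_threshold - abs(self.plateau_slope_)
            > 1e-9 * self.slope_threshold
        )
        self.pi_ = surface_pressure(self.plateau_ift_, trace.ift_ref_mN_per_m)
        negative = self.pi_ < 0
        if negative:
            warnings.warn(
                "negative surface pressure (plateau IFT above reference); "
                "reported as-is",
                stacklevel=2,
            )
        self.result_ = SurfacePressureResult(
            pi_mN_per_m=self.pi_,
            plateau_ift_mN_per_m=self.plateau_ift_,
            plateau_reached=self.plateau_reached_,
            plateau_slope_mN_per_m_per_min=self.plateau_slope_,
            window_s=self.window_s,
            slope_threshold_mN_per_m_per_min=self.slope_threshold,
            negative_pi=negative,
        )
        return self


def steady_state(
    trace: IFTTrace,
    window: float = PLATEAU_WINDOW_S,
    slope_threshold: float = PLATEAU_SLOPE_MN_PER_M_PER_MIN,
) -> SurfacePressureResult:
    """Plateau detection; see :class:`SteadyStateDetector`."""
    return SteadyStateDetector(window_s=window, slope_threshold=slope_threshold).fit(
        trace
    ).result_


def cooperativity(pi_sim, pi_particle: float, pi_enzyme: float) -> CooperativityResult:
    """Cooperativity factor alpha = (pi_sim - pi_particle) / pi_enzyme.

    ``pi_sim`` may be an array (time-resolved alpha); ``pi_particle`` and
    ``pi_enzyme`` are plateau values in mN/m.  alpha is affine in
    ``pi_sim`` with slope 1/pi_enzyme.  Raises if ``pi_enzyme <= 0``
    (cooperativity is undefined without enzyme surface activity).
    """
    pi_enzyme = float(pi_enzyme)
    pi_particle = float(pi_particle)
    if not np.isfinite(pi_enzyme) or pi_enzyme <= 0:
        raise ValueError("undefined cooperativity: pi_enzyme must be positive")
    pi_sim = np.asarray(pi_sim, dtype=float)
    alpha = (pi_sim - pi_particle) / pi_enzyme
    if alpha.ndim == 0:
        alpha = float(alpha)
        pi_sim = float(pi_sim)
    return CooperativityResult(
        alpha=alpha,
        pi_sim_mN_per_m=pi_sim,
        pi_particle_mN_per_m=pi_particle,
        pi_enzyme_mN_per_m=pi_enzyme,
    )


def desorption_energy(
    r: float, ift_ow: float, theta: float, sign: int = 1
) -> DesorptionEnergyResult:
    """Spherical-particle detachment energy from a liquid-liquid interface.

    E = pi r^2 * IFT_o/w * (1 - sign*cos(theta))^2, in joules, with ``r``
    in metres, ``ift_ow`` in N/m and the three-phase contact angle
    ``theta`` in degrees.  ``sign`` selects the phase the particle is
    removed into (+1: into the phase the contact angle is measured
    through; -1: the opposite phase); both conventions appear in the
    literature and the energy is symmetric under (sign, theta) ->
    (-sign, 180 - theta).
    """
    if r < 0:
        raise ValueError("radius must be nonnegative")
    if not (0.0 <= theta <= 180.0):
        raise ValueError("contact angle must be within [0, 180] degrees")
    if ift_ow <= 0:
        raise ValueError("ift_ow must be positive")
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    energy = np.pi * r**2 * ift_ow * (1.0 - sign * np.cos(np.deg2rad(theta))) ** 2
    return DesorptionEnergyResult(
        energy_J=float(energy),
        radius_m=r,
        ift_ow_N_per_m=ift_ow,
        contact_angle_deg=theta,
        sign=sign,
    )
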