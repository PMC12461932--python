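"""Interfacial oscillatory shear rheology.

A harmonic strain drive gamma(t) = gamma_A sin(omega t) produces a stress
response tau(t) = tau_A sin(omega t + delta); the phase angle delta
classifies the interface (0 deg purely elastic, 90 deg purely viscous).
The interfacial storage and loss moduli follow from the amplitude ratio:

    Gi'  = (tau_A / gamma_A) cos(delta)      [Pa*m]
    Gi'' = (tau_A / gamma_A) sin(delta)      [Pa*m]

with gamma_A as a dimensionless fraction (user-facing strain is percent).
Amplitude sweeps are analysed for the LVE plateau, the yield point
gamma_y (onset of structural weakening, a 5 % drop of G' from the
plateau by default) and the flow point gamma_f (the G' = G'' crossover,
located by linear interpolation in log-log coordinates).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import AmplitudeSweep, ModuliPoint, OscillationTrace, SweepAnalysis

__all__ = [
    "HarmonicFit",
    "fit_harmonic",
    "moduli",
    "time_test",
    "saturation_time",
    "AmplitudeSweepAnalyzer",
    "lve_plateau",
    "yield_point",
    "flow_point",
]


def _amp_phase(t: np.ndarray, y: np.ndarray, omega: float) -> tuple[float, float]:
    """Least-squares projection of y onto {sin wt, cos wt, 1}.

    Returns (amplitude, phase in radians) of y = A sin(wt + phi) + c.
    """
    basis = np.column_stack([np.sin(omega * t), np.cos(omega * t), np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    a, b, _ = coef
    return float(np.hypot(a, b)), float(np.arctan2(b, a))


class HarmonicFit(BaseEstimator):
    """Amplitude/phase extraction from one oscillation block.

    Strain and stress are each projected onto a sin/cos/constant basis at
    the known drive frequency by linear least squares (the instrument
    frequency is always known, so no spectral search is needed).  The
    phase angle is the stress phase minus the strain phase, reported in
    degrees and wrapped to [0, 180); values within [0, 90] are physical
    for a passive interface.

    Fitted attributes: ``gamma_A_`` (percent), ``tau_A_`` (Pa*m),
    ``delta_deg_``, ``physical_`` and ``harmonic_`` (False when less than
    ``min_drive_power`` of the stress variance sits at the drive
    frequency — a non-harmonic response).
    """

    def __init__(self, min_periods: float = 2.0, min_drive_power: float = 0.5):
        self.min_periods = min_periods
        self.min_drive_power = min_drive_power

    def fit(self, trace: OscillationTrace) -> "HarmonicFit":
        if trace.n_periods < self.min_periods:
            raise ValueError(
                f"trace spans {trace.n_periods:.2f} periods "
                f"< required {self.min_periods}"
            )
        t = trace.time_s
        omega = trace.omega_rad_per_s
        self.gamma_A_, strain_phase = _amp_phase(t, trace.strain_pct, omega)
        self.tau_A_, stress_phase = _amp_phase(t, trace.stress_Pa_m, omega)

        drive_power = 0.5 * self.tau_A_**2
        total_power = float(np.var(trace.stress_Pa_m))
        self.harmonic_ = bool(
            total_power <= 0 or drive_power >= self.min_drive_power * total_power
        )
        if not self.harmonic_:
            warnings.warn(
                "not a harmonic response: stress power at the drive frequency "
                f"is {drive_power / total_power:.0%} of the total",
                stacklevel=2,
            )

        delta = np.rad2deg(stress_phase - strain_phase) % 360.0
        if delta >= 180.0:
            delta -= 180.0
        if delta > 180.0 - 1e-6:  # -epsilon phase jitter wraps to just under 180
            delta = 0.0
        self.delta_deg_ = float(delta)
        self.physical_ = bool(0.0 <= self.delta_deg_ <= 90.0)
        return self


def fit_harmonic(trace: OscillationTrace) -> tuple[float, float, float]:
    """Return (gamma_A percent, tau_A Pa*m, delta degrees) for one block."""
    fit = HarmonicFit().fit(trace)
    return fit.gamma_A_, fit.tau_A_, fit.delta_deg_


def moduli(
    gamma_A: float, tau_A: float, delta: float, timestamp: float = 0.0
) -> ModuliPoint:
    """Interfacial storage/loss moduli from amplitude ratio and phase.

    ``gamma_A`` in percent, ``tau_A`` in Pa*m, ``delta`` in degrees.
    """
    if gamma_A <= 0:
        raise ValueError("gamma_A must be positive")
    gamma_frac = gamma_A / 100.0
    ratio = tau_A / gamma_frac
    d = np.deg2rad(delta)
    return ModuliPoint(
        gp_Pa_m=float(ratio * np.cos(d)),
        gpp_Pa_m=float(ratio * np.sin(d)),
        delta_deg=float(delta),
        gamma_A_pct=float(gamma_A),
        tau_A_Pa_m=float(tau_A),
        timestamp_s=timestamp,
        physical=bool(0.0 <= delta <= 90.0),
    )


def analyze_trace(trace: OscillationTrace) -> ModuliPoint:
    """Harmonic fit plus moduli for one oscillation block."""
    gamma_A, tau_A, delta = fit_harmonic(trace)
    return moduli(gamma_A, tau_A, delta, timestamp=trace.timestamp_s)


def time_test(
    traces: list[OscillationTrace], amplitude_rtol: float = 0.05
) -> pd.DataFrame:
    """Layer build-up curve: one moduli point per oscillation block.

    All blocks must share the drive frequency and strain amplitude (the
    protocol holds gamma = 0.1 % and omega = 1 rad/s while the layer
    forms).  Returns a DataFrame ordered by timestamp with columns
    time_s, gp_Pa_m, gpp_Pa_m, delta_deg, gamma_A_pct, tau_A_Pa_m.
    """
    if not traces:
        raise ValueError("no traces given")
    omegas = np.array([tr.omega_rad_per_s for tr in traces])
    if not np.allclose(omegas, omegas[0], rtol=1e-9):
        raise ValueError("traces have inconsistent drive frequencies")
    points = [analyze_trace(tr) for tr in traces]
    amps = np.array([p.gamma_A_pct for p in points])
    ref = np.median(amps)
    bad = np.nonzero(np.abs(amps - ref) > amplitude_rtol * ref)[0]
    if bad.size:
        raise ValueError(
            "inconsistent strain amplitudes in traces at indices "
            f"{bad.tolist()} (amplitudes {amps[bad].tolist()} vs median {ref:.4g})"
        )
    frame = pd.DataFrame(
        {
            "time_s": [p.timestamp_s for p in points],
            "gp_Pa_m": [p.gp_Pa_m for p in points],
            "gpp_Pa_m": [p.gpp_Pa_m for p in points],
            "delta_deg": [p.delta_deg for p in points],
            "gamma_A_pct": [p.gamma_A_pct for p in points],
            "tau_A_Pa_m": [p.tau_A_Pa_m for p in points],
        }
    ).sort_values("time_s", ignore_index=True)
    return frame


def saturation_time(
    times: np.ndarray,
    values: np.ndarray,
    window: float,
    slope_threshold: float,
) -> float | None:
    """Earliest time from which the trailing-window slope stays subcritical.

    Same pattern as the tensiometry plateau criterion: at each sample
    whose trailing window of length ``window`` is fully covered, the
    least-squares slope of ``values`` over that window is computed; the
    saturation time is the earliest sample time such that |slope| <
    ``slope_threshold`` there and at every later sample.  Returns None if
    the curve never saturates.  Units: slope threshold per second.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.full(times.size, False)
    for i, t_i in enumerate(times):
        mask = (times >= t_i - window) & (times <= t_i)
        if times[mask].size < 2 or t_i - times[0] < window:
            continue
        slope = np.polyfit(times[mask], values[mask], 1)[0]
        ok[i] = abs(slope) < slope_threshold
    # earliest index from which ok holds through the end
    idx = None
    for i in range(times.size - 1, -1, -1):
        if ok[i]:
            idx = i
        else:
            break
    return None if idx is None else float(times[idx])


class AmplitudeSweepAnalyzer(BaseEstimator):
    """LVE plateau, yield point and flow point of an amplitude sweep.

    * LVE plateau: mean G' over the maximal leading run of points whose
      G' stays within ``lve_tolerance`` (relative) of the first point.
    * Yield point gamma_y: smallest strain where G' has dropped below
      (1 - ``yield_drop_fraction``) of the plateau, refined by linear
      interpolation of log G' against log strain between the bracketing
      grid points.  The 5 % default is the common rheometry convention;
      the onset of structural weakening has no universal definition.
    * Flow point gamma_f: strain of the G' = G'' crossover, interpolated
      linearly in log-log coordinates between the bracketing points; when
      several crossings exist, the first one with G' decreasing is taken.
      The flow point is invariant under a common rescaling of both
      moduli.

    Fitted attributes: ``gp_lve_``, ``gamma_y_``, ``gamma_f_``,
    ``no_yield_``, ``no_flow_point_``, ``flags_``, ``result_``.
    """

    def __init__(self, lve_tolerance: float = 0.05, yield_drop_fraction: float = 0.05):
        self.lve_tolerance = lve_tolerance
        self.yield_drop_fraction = yield_drop_fraction

    def fit(self, sweep: AmplitudeSweep) -> "AmplitudeSweepAnalyzer":
        if sweep.strain_pct.size < 3:
            raise ValueError("sweep needs at least 3 points")
        flags: list[str] = []
        gp = sweep.gp_Pa_m
        gpp = sweep.gpp_Pa_m
        gamma = sweep.strain_pct
        if not np.isfinite(gp[0]) or gp[0] <= 0:
            raise ValueError("first sweep point has no physical storage modulus")

        # ---- LVE plateau
        within = np.abs(gp - gp[0]) <= self.lve_tolerance * gp[0]
        run_end = int(np.argmin(within)) if not within.all() else within.size
        if run_end == 0:
            run_end = 1
        if run_end == 1:
            warnings.warn(
                "LVE run is a single point (immediate decay)", stacklevel=2
            )
            flags.append("single-point LVE")
        self.gp_lve_ = float(np.mean(gp[:run_end]))

        # ---- yield point
        threshold = (1.0 - self.yield_drop_fraction) * self.gp_lve_
        below = np.nonzero(gp < threshold)[0]
        if below.size == 0:
            self.gamma_y_ = None
            self.no_yield_ = True
            flags.append("no yield detected")
        else:
            i = int(below[0])
            self.no_yield_ = False
            if i == 0:
                self.gamma_y_ = float(gamma[0])
                flags.append("yield below first grid point")
            else:
                self.gamma_y_ = float(
                    _loglog_crossing(
                        gamma[i - 1], gamma[i], gp[i - 1], gp[i], threshold
                    )
                )

        # ---- flow point
        self.gamma_f_ = None
        self.no_flow_point_ = True
        diff = np.log(gp) - np.log(np.clip(gpp, 1e-300, None))
        for i in range(diff.size - 1):
            if diff[i] > 0 >= diff[i + 1] and gp[i + 1] < gp[i]:
                x0, x1 = np.log(gamma[i]), np.log(gamma[i + 1])
                frac = diff[i] / (diff[i] - diff[i + 1])
                self.gamma_f_ = float(np.exp(x0 + frac * (x1 - x0)))
                self.no_flow_point_ = False
                break
        if self.no_flow_point_:
            flags.append("no flow point (moduli do not cross)")

        self.flags_ = tuple(flags)
        self.result_ = SweepAnalysis(
            gp_lve_Pa_m=self.gp_lve_,
            gamma_y_pct=self.gamma_y_,
            gamma_f_pct=self.gamma_f_,
            no_yield=self.no_yield_,
            no_flow_point=self.no_flow_point_,
            flags=self.flags_,
        )
        return self


def _loglog_crossing(x0, x1, y0, y1, level) -> float:
    """Strain where a log-log linear segment crosses a modulus level."""
    lx0, lx1 = np.log(x0), np.log(x1)
    ly0, ly1 = np.log(y0), np.log(y1)
    frac = (np.log(level) - ly0) / (ly1 - ly0)
    return float(np.exp(lx0 + frac * (lx1 - lx0)))


def lve_plateau(sweep: AmplitudeSweep, tolerance: float = 0.05) -> float:
    """Mean G' over the leading strain-independent run; see analyzer."""
    return AmplitudeSweepAnalyzer(lve_tolerance=tolerance).fit(sweep).gp_lve_


def yield_point(sweep: AmplitudeSweep, drop_fraction: float = 0.05) -> float | None:
    """Yield strain gamma_y in percent, or None when no yield is detected."""
    return AmplitudeSweepAnalyzer(yield_drop_fraction=drop_fraction).fit(sweep).gamma_y_


def flow_point(sweep: AmplitudeSweep) -> float | None:
    """Flow strain gamma_f (G' = G'' crossover) in percent, or None."""
    return AmplitudeSweepAnalyzer().fit(sweep).gamma_f_
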