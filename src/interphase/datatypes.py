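"""Typed containers shared across the analysis modules.

Unit conventions (encoded in field names):

* time in seconds (``_s``), interfacial tension and surface pressure in
  mN/m (``_mN_per_m``), strain in percent (``_pct``), interfacial shear
  stress and moduli in Pa·m (``_Pa_m``), lengths in micrometres
  (``_um``), concentrations in g/L (``_g_per_L``).
* Strain is user-facing in percent everywhere; computations that need the
  dimensionless strain divide by 100 internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "GroundTruth",
    "IFTTrace",
    "OscillationTrace",
    "AmplitudeSweep",
    "ModuliPoint",
    "SweepAnalysis",
    "SurfacePressureResult",
    "CooperativityResult",
    "DesorptionEnergyResult",
    "DropletImage",
    "CalibrationCurve",
    "RadialProfileSet",
    "DiameterProfile",
    "DropletMetrics",
    "EmulsionSummary",
]


@dataclass(frozen=True)
class GroundTruth:
    """Record of the generating parameters of one synthetic object.

    Every generator returns a ``GroundTruth`` alongside its data;
    regenerating with the same seed reproduces the data bit-for-bit.
    """

    kind: str
    seed: int | None
    params: dict[str, Any]

    def __getitem__(self, key: str) -> Any:
        return self.params[key]


@dataclass
class IFTTrace:
    """Time-stamped interfacial tension record from pendant-drop tensiometry."""

    time_s: np.ndarray
    ift_mN_per_m: np.ndarray
    ift_ref_mN_per_m: float = 8.1  # clean octanol/water reference
    ph: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.ift_mN_per_m = np.asarray(self.ift_mN_per_m, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.ift_mN_per_m.shape:
            raise ValueError("time and IFT must be 1-D arrays of equal length")
        if self.time_s.size < 2:
            raise ValueError("trace needs at least two samples")
        if not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.ift_mN_per_m)) or np.any(self.ift_mN_per_m <= 0):
            raise ValueError("IFT values must be finite and positive")

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


@dataclass
class OscillationTrace:
    """Synchronised strain/stress time series at a known drive frequency."""

    time_s: np.ndarray
    strain_pct: np.ndarray
    stress_Pa_m: np.ndarray
    omega_rad_per_s: float
    timestamp_s: float = 0.0  # wall-clock position of this block in a time test
    label: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.strain_pct = np.asarray(self.strain_pct, dtype=float)
        self.stress_Pa_m = np.asarray(self.stress_Pa_m, dtype=float)
        n = self.time_s.size
        if self.strain_pct.size != n or self.stress_Pa_m.size != n:
            raise ValueError("time, strain and stress must have equal length")
        if not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time must be strictly increasing")
        if self.omega_rad_per_s <= 0:
            raise ValueError("omega must be positive")

    @property
    def n_periods(self) -> float:
        return float(
            (self.time_s[-1] - self.time_s[0]) * self.omega_rad_per_s / (2.0 * np.pi)
        )


@dataclass(frozen=True)
class ModuliPoint:
    """Interfacial moduli derived from one oscillation block.

    ``gp`` and ``gpp`` are the storage and loss moduli Gi' and Gi'' in
    Pa·m, computed from the stress/strain amplitude ratio and the phase
    angle delta.
    """

    gp_Pa_m: float
    gpp_Pa_m: float
    delta_deg: float
    gamma_A_pct: float
    tau_A_Pa_m: float
    timestamp_s: float = 0.0
    physical: bool = True  # delta within [0, 90] degrees


@dataclass
class AmplitudeSweep:
    """Per-strain-amplitude table of interfacial storage and loss moduli."""

    strain_pct: np.ndarray
    gp_Pa_m: np.ndarray
    gpp_Pa_m: np.ndarray
    omega_rad_per_s: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        self.strain_pct = np.asarray(self.strain_pct, dtype=float)
        self.gp_Pa_m = np.asarray(self.gp_Pa_m, dtype=float)
        self.gpp_Pa_m = np.asarray(self.gpp_Pa_m, dtype=float)
        n = self.strain_pct.size
        if self.gp_Pa_m.size != n or self.gpp_Pa_m.size != n:
            raise ValueError("strain, G' and G'' must have equal length")
        if not np.all(np.diff(self.strain_pct) > 0):
            raise ValueError("strain amplitudes must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strain_pct": self.strain_pct,
                "gp_Pa_m": self.gp_Pa_m,
                "gpp_Pa_m": self.gpp_Pa_m,
            }
        )


@dataclass(frozen=True)
class SweepAnalysis:
    """LVE plateau, yield point and flow point of one amplitude sweep."""

    gp_lve_Pa_m: float
    gamma_y_pct: float | None
    gamma_f_pct: float | None
    no_yield: bool = False
    no_flow_point: bool = False
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class SurfacePressureResult:
    """Plateau state of an IFT trace and the resulting surface pressure."""

    pi_mN_per_m: float
    plateau_ift_mN_per_m: float
    plateau_reached: bool
    plateau_slope_mN_per_m_per_min: float
    window_s: float
    slope_threshold_mN_per_m_per_min: float
    negative_pi: bool = False


@dataclass(frozen=True)
class CooperativityResult:
    """Adsorption cooperativity alpha = (Pi_sim - Pi_particle) / Pi_enzyme."""

    alpha: float | np.ndarray
    pi_sim_mN_per_m: float | np.ndarray
    pi_particle_mN_per_m: float
    pi_enzyme_mN_per_m: float


@dataclass(frozen=True)
class DesorptionEnergyResult:
    """Detachment energy of a spherical particle from the L/L interface."""

    energy_J: float
    radius_m: float
    ift_ow_N_per_m: float
    contact_angle_deg: float
    sign: int


@dataclass
class DropletImage:
    """Single-plane grayscale confocal image with physical pixel size."""

    intensity: np.ndarray
    pixel_size_um: float
    label: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2 or self.intensity.size == 0:
            raise ValueError("intensity must be a nonempty 2-D grid")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be nonnegative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear fluorescence-intensity-to-concentration map."""

    gain: float  # intensity per g/L
    offset: float  # intensity
    r_squared: float
    n_standards: int

    @property
    def usable(self) -> bool:
        return self.gain > 0


@dataclass
class RadialProfileSet:
    """Diameter line profiles rotated around the droplet center.

    ``profiles`` has one row per rotation angle; out-of-frame samples are
    NaN (truncated profiles) and excluded from averages.
    """

    positions_um: np.ndarray  # signed, 0 at the droplet center
    angles_deg: np.ndarray
    profiles: np.ndarray  # (n_angles, n_positions)
    truncated: bool = False


@dataclass
class DiameterProfile:
    """Averaged signed diameter profile (intensity or concentration)."""

    positions_um: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    units: str = "intensity"  # "intensity" or "g_per_L"
    clip_fraction: float = 0.0  # fraction of samples clipped at 0 g/L

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if not (self.positions_um.size == self.values.size == self.counts.size):
            raise ValueError("positions, values and counts must have equal length")


@dataclass(frozen=True)
class DropletMetrics:
    """Per-droplet interfacial layer quantities."""

    diameter_um: float
    interface_conc_g_per_L: float
    interface_thickness_um: float
    bulk_conc_g_per_L: float
    peak_position_left_um: float
    peak_position_right_um: float
    thickness_left_um: float
    thickness_right_um: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class EmulsionSummary:
    """Mean +/- SD of droplet metrics over an emulsion (Table-style)."""

    table: pd.DataFrame  # index: metric; columns: mean, sd
    n_droplets: int
    excluded: tuple[int, ...] = ()
    flags: tuple[str, ...] = ()
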