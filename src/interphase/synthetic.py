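"""Instrument-like synthetic data with known ground truth.

Phenomenological generators for every input the analysis modules
consume: interfacial-tension decays, oscillatory strain/stress blocks,
amplitude sweeps, confocal droplet images and calibration standards.
All randomness is seeded explicitly; identical seeds reproduce the data
bit-for-bit.  No adsorption thermodynamics or photophysics is simulated
— the generators only reproduce the phenomenology the analyses must be
robust to (decay to a plateau, phase-lagged harmonics, an LVE plateau
with a modulus crossover, a bright asymmetric interfacial ring with
photon noise).
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    AmplitudeSweep,
    DropletImage,
    GroundTruth,
    IFTTrace,
    OscillationTrace,
)
from .presets import REF_CONC_G_PER_L, droplet_preset

__all__ = [
    "gen_ift_trace",
    "gen_oscillation_trace",
    "gen_amplitude_sweep",
    "amplitude_sweep_model",
    "gen_droplet_image",
    "gen_droplet_image_preset",
    "gen_calibration_standards",
    "ring_decay_lengths",
]


def gen_ift_trace(
    ift0: float = 8.1,
    ift_inf: float = 5.0,
    tau_fast: float = 60.0,
    tau_slow: float = 1500.0,
    weight_fast: float = 0.6,
    duration: float = 7000.0,
    dt: float = 1.0,
    noise_sd: float = 0.02,
    seed: int | None = 0,
    ift_ref: float = 8.1,
    ph: float | None = None,
) -> tuple[IFTTrace, GroundTruth]:
    """Bi-exponential interfacial-tension decay to a plateau.

    IFT(t) = ift_inf + (ift0 - ift_inf) * [w e^(-t/tau_fast)
             + (1-w) e^(-t/tau_slow)] + Gaussian noise.

    The bi-exponential form reproduces the typical adsorption
    phenomenology of an initial rapid drop followed by a slower decline;
    it is a data model, not an adsorption theory.  Units: mN/m and s.
    """
    if dt <= 0 or duration <= 0:
        raise ValueError("dt and duration must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if not (ift0 >= ift_inf >= 0):
        raise ValueError("require ift0 >= ift_inf >= 0")
    if tau_fast >= tau_slow:
        raise ValueError("require tau_fast < tau_slow")
    if not (0.0 <= weight_fast <= 1.0):
        raise ValueError("weight_fast must be within [0, 1]")

    t = np.arange(0.0, duration + 0.5 * dt, dt)
    decay = weight_fast * np.exp(-t / tau_fast) + (1.0 - weight_fast) * np.exp(
        -t / tau_slow
    )
    ift = ift_inf + (ift0 - ift_inf) * decay
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ift = ift + rng.normal(0.0, noise_sd, size=t.size)
        # keep the trace physical (IFT strictly positive) for extreme draws
        ift = np.clip(ift, 1e-6, None)
    trace = IFTTrace(t, ift, ift_ref_mN_per_m=ift_ref, ph=ph)
    truth = GroundTruth(
        kind="ift_trace",
        seed=seed,
        params=dict(
            ift0=ift0,
            ift_inf=ift_inf,
            tau_fast=tau_fast,
            tau_slow=tau_slow,
            weight_fast=weight_fast,
            duration=duration,
            dt=dt,
            noise_sd=noise_sd,
            ift_ref=ift_ref,
        ),
    )
    return trace, truth


def gen_oscillation_trace(
    gamma_A: float = 0.1,
    omega: float = 1.0,
    delta: float = 30.0,
    modulus_magnitude: float = 2e-3,
    duration: float = 10 * 2 * np.pi,
    sample_rate: float = 16.0,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    timestamp: float = 0.0,
) -> tuple[OscillationTrace, GroundTruth]:
    """Harmonic strain drive and phase-lagged stress response.

    strain(t) = gamma_A sin(omega t) in percent; stress(t) =
    tau_A sin(omega t + delta) with tau_A = modulus_magnitude *
    gamma_A/100 (the modulus magnitude multiplies the dimensionless
    strain).  ``noise_sd`` is Gaussian stress noise as a fraction of
    tau_A.  Requires at least 4 samples per drive period.
    """
    if not (0.0 <= delta <= 90.0):
        raise ValueError("delta must be within [0, 90] degrees")
    if omega <= 0:
        raise ValueError("omega must be positive")
    if duration <= 0 or sample_rate <= 0:
        raise ValueError("duration and sample_rate must be positive")
    samples_per_period = sample_rate * 2.0 * np.pi / omega
    if samples_per_period < 4.0:
        raise ValueError(
            f"undersampled trace: {samples_per_period:.2f} samples/period < 4"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")

    t = np.arange(0.0, duration, 1.0 / sample_rate)
    tau_A = modulus_magnitude * gamma_A / 100.0
    strain = gamma_A * np.sin(omega * t)
    stress = tau_A * np.sin(omega * t + np.deg2rad(delta))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stress = stress + rng.normal(0.0, noise_sd * tau_A, size=t.size)
    trace = OscillationTrace(t, strain, stress, omega, timestamp_s=timestamp)
    truth = GroundTruth(
        kind="oscillation_trace",
        seed=seed,
        params=dict(
            gamma_A=gamma_A,
            omega=omega,
            delta=delta,
            modulus_magnitude=modulus_magnitude,
            tau_A=tau_A,
            duration=duration,
            sample_rate=sample_rate,
            noise_sd=noise_sd,
        ),
    )
    return trace, truth


def amplitude_sweep_model(
    gamma_pct: np.ndarray | float,
    gp_lve: float,
    gpp_lve: float,
    gamma_y: float,
    gamma_f: float,
    drop_fraction: float = 0.05,
    p: float = 2.0,
    m: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free amplitude-sweep curves G'(gamma), G''(gamma).

    G' is a smooth log-strain sigmoid, ``gp_lve / (1 + (gamma/gamma_s)^p)``,
    with ``gamma_s`` chosen so that G' has dropped by ``drop_fraction``
    exactly at ``gamma_y`` (the yield point).  The loss modulus is built
    as G'' = G' * tan(delta(gamma)) with a loss tangent that rises
    monotonically from its LVE value ``gpp_lve/gp_lve`` through exactly 1
    at ``gamma_f``, which places the single G' = G'' crossing at the flow
    point by construction for any gel-like layer (gp_lve > gpp_lve).
    """
    gamma = np.asarray(gamma_pct, dtype=float)
    gamma_s = gamma_y / (1.0 / (1.0 - drop_fraction) - 1.0) ** (1.0 / p)
    gp = gp_lve / (1.0 + (gamma / gamma_s) ** p)
    tan_lve = gpp_lve / gp_lve
    # L(gamma_f) = 1 exactly; L -> 0 as gamma -> 0; strictly increasing
    lam = np.log1p((gamma / gamma_f) ** m) / np.log(2.0)
    gpp = gp * tan_lve ** (1.0 - lam)
    return gp, gpp


def gen_amplitude_sweep(
    gp_lve: float = 2e-3,
    gpp_lve: float = 5e-4,
    gamma_y: float = 1.65,
    gamma_f: float = 13.9,
    strain_grid: np.ndarray | None = None,
    seed: int | None = 0,
    noise_sd: float = 0.0,
    drop_fraction: float = 0.05,
    omega: float = 1.0,
) -> tuple[AmplitudeSweep, GroundTruth]:
    """Amplitude sweep with LVE plateau, prescribed yield and flow points.

    ``strain_grid`` defaults to 10 log-spaced points per decade from 0.01
    to 100 % strain.  ``noise_sd`` is multiplicative Gaussian noise as a
    fraction of each modulus value.  Preconditions: gp_lve > gpp_lve
    (gel-like LVE) and 0.01 <= gamma_y < gamma_f <= 100 with gamma_f
    inside the grid.
    """
    if strain_grid is None:
        strain_grid = np.logspace(-2, 2, 41)
    strain_grid = np.asarray(strain_grid, dtype=float)
    if not gp_lve > gpp_lve > 0:
        raise ValueError("require gp_lve > gpp_lve > 0 (gel-like LVE)")
    if not (0.01 <= gamma_y < gamma_f <= 100.0):
        raise ValueError("require 0.01 <= gamma_y < gamma_f <= 100")
    if not (strain_grid[0] <= gamma_f <= strain_grid[-1]):
        raise ValueError("gamma_f lies outside the strain grid")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")

    gp, gpp = amplitude_sweep_model(
        strain_grid, gp_lve, gpp_lve, gamma_y, gamma_f, drop_fraction=drop_fraction
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        gp = gp * (1.0 + rng.normal(0.0, noise_sd, size=gp.size))
        gpp = gpp * (1.0 + rng.normal(0.0, noise_sd, size=gpp.size))
        gp = np.clip(gp, 1e-12, None)
        gpp = np.clip(gpp, 1e-12, None)
    sweep = AmplitudeSweep(strain_grid, gp, gpp, omega_rad_per_s=omega)
    truth = GroundTruth(
        kind="amplitude_sweep",
        seed=seed,
        params=dict(
            gp_lve=gp_lve,
            gpp_lve=gpp_lve,
            gamma_y=gamma_y,
            gamma_f=gamma_f,
            drop_fraction=drop_fraction,
            noise_sd=noise_sd,
            omega=omega,
        ),
    )
    return sweep, truth


def ring_decay_lengths(
    ring_width: float,
    peak_conc: float,
    bulk_conc: float,
    background_conc: float,
    inner_outer_asymmetry: float,
    ref_conc: float = REF_CONC_G_PER_L,
) -> tuple[float, float]:
    """Gaussian decay lengths (inner, outer) enforcing the width-at-level.

    The interfacial ring is a two-sided Gaussian with distinct inner and
    outer decay lengths sigma_in = asymmetry * sigma_out.  The lengths
    are solved so that the full width of the concentration peak measured
    at the ``ref_conc`` level equals ``ring_width`` exactly.
    """
    if peak_conc <= ref_conc:
        raise ValueError(
            f"ring width at the {ref_conc} g/L level is unreachable: "
            f"peak_conc={peak_conc} g/L does not exceed it"
        )
    if ref_conc <= bulk_conc or ref_conc <= background_conc:
        raise ValueError("ref level must exceed bulk and background levels")
    k_in = np.sqrt(2.0 * np.log((peak_conc - bulk_conc) / (ref_conc - bulk_conc)))
    k_out = np.sqrt(
        2.0 * np.log((peak_conc - background_conc) / (ref_conc - background_conc))
    )
    sigma_out = ring_width / (inner_outer_asymmetry * k_in + k_out)
    return inner_outer_asymmetry * sigma_out, sigma_out


def droplet_concentration_field(
    r_um: np.ndarray,
    diameter: float,
    sigma_in: float,
    sigma_out: float,
    peak_conc: float,
    bulk_conc: float,
    background_conc: float,
) -> np.ndarray:
    """Radial concentration field of a droplet with an interfacial ring."""
    r0 = diameter / 2.0
    inner = bulk_conc + (peak_conc - bulk_conc) * np.exp(
        -0.5 * ((r_um - r0) / sigma_in) ** 2
    )
    outer = background_conc + (peak_conc - background_conc) * np.exp(
        -0.5 * ((r_um - r0) / sigma_out) ** 2
    )
    return np.where(r_um <= r0, inner, outer)


def gen_droplet_image(
    diameter: float = 5.17,
    ring_width: float = 0.75,
    peak_conc: float = 1.56,
    bulk_conc: float = 0.098,
    background_conc: float = 0.0,
    inner_outer_asymmetry: float = 2.0,
    pixel_size: float = 0.1,
    gain: float = 200.0,
    noise_model: str = "poisson",
    seed: int | None = 0,
    gaussian_sd: float = 5.0,
    margin_um: float = 1.5,
    center_offset_px: tuple[float, float] = (0.0, 0.0),
    ref_conc: float = REF_CONC_G_PER_L,
) -> tuple[DropletImage, GroundTruth]:
    """Confocal-like image of one droplet with a bright interfacial ring.

    The concentration field is radially symmetric: background outside the
    droplet, a two-sided Gaussian peak of height ``peak_conc`` centred at
    radius ``diameter/2`` whose width at the ``ref_conc`` level equals
    ``ring_width`` exactly, and an interior plateau at ``bulk_conc``.
    The signal decays more sharply on the outer (oil-facing) side than on
    the inner (aqueous) side: ``inner_outer_asymmetry`` > 1 is the ratio
    of inner to outer decay lengths.  Intensity = ``gain`` * concentration
    with selectable photon noise (``poisson``) or additive ``gaussian``
    noise of SD ``gaussian_sd`` intensity counts; ``none`` disables noise.

    Lengths in micrometres, concentrations in g/L.  Returns the image and
    the generating ground truth (including the subpixel center in pixel
    coordinates).
    """
    if diameter <= 2.0 * ring_width:
        raise ValueError("require diameter > 2 * ring_width")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if not peak_conc > bulk_conc >= 0:
        raise ValueError("require peak_conc > bulk_conc >= 0")
    if noise_model not in ("none", "gaussian", "poisson"):
        raise ValueError("noise_model must be one of none|gaussian|poisson")

    sigma_in, sigma_out = ring_decay_lengths(
        ring_width, peak_conc, bulk_conc, background_conc, inner_outer_asymmetry,
        ref_conc=ref_conc,
    )

    half_px = int(np.ceil((diameter / 2.0 + margin_um) / pixel_size))
    n = 2 * half_px + 1  # odd: nominal center on a pixel center
    center = (half_px + center_offset_px[0], half_px + center_offset_px[1])
    rows = np.arange(n)[:, None]
    cols = np.arange(n)[None, :]
    r_um = pixel_size * np.hypot(rows - center[0], cols - center[1])
    conc = droplet_concentration_field(
        r_um, diameter, sigma_in, sigma_out, peak_conc, bulk_conc, background_conc
    )
    signal = gain * conc
    if noise_model == "poisson":
        rng = np.random.default_rng(seed)
        intensity = rng.poisson(signal).astype(float)
    elif noise_model == "gaussian":
        rng = np.random.default_rng(seed)
        intensity = np.clip(signal + rng.normal(0.0, gaussian_sd, signal.shape), 0, None)
    else:
        intensity = signal
    image = DropletImage(intensity, pixel_size_um=pixel_size)
    truth = GroundTruth(
        kind="droplet_image",
        seed=seed,
        params=dict(
            diameter=diameter,
            ring_width=ring_width,
            peak_conc=peak_conc,
            bulk_conc=bulk_conc,
            background_conc=background_conc,
            inner_outer_asymmetry=inner_outer_asymmetry,
            sigma_in=sigma_in,
            sigma_out=sigma_out,
            pixel_size=pixel_size,
            gain=gain,
            noise_model=noise_model,
            ref_conc=ref_conc,
            center_row_px=center[0],
            center_col_px=center[1],
        ),
    )
    return image, truth


def gen_droplet_image_preset(
    preset: str, seed: int | None = 0, **overrides
) -> tuple[DropletImage, GroundTruth]:
    """Generate a droplet image from a named condition preset.

    Presets carry the per-condition mean diameter, peak concentration,
    ring width and bulk concentration; any generator argument can be
    overridden by keyword.
    """
    params = droplet_preset(preset)
    kwargs = dict(
        diameter=params["diameter_um"],
        ring_width=params["ring_width_um"],
        peak_conc=params["peak_conc_g_per_L"],
        bulk_conc=params["bulk_conc_g_per_L"],
    )
    kwargs.update(overrides)
    return gen_droplet_image(seed=seed, **kwargs)


def gen_calibration_standards(
    concs: np.ndarray | list[float],
    gain: float = 200.0,
    offset: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> tuple[list[tuple[float, float]], GroundTruth]:
    """Calibration standards: mean intensity at known concentrations.

    intensity = gain * conc + offset + Gaussian noise.  Requires at least
    two distinct concentrations.
    """
    concs = np.asarray(concs, dtype=float)
    if np.unique(concs).size < 2:
        raise ValueError("need at least 2 distinct concentrations")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    intensity = gain * concs + offset
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, size=concs.size)
    pairs = list(zip(concs.tolist(), intensity.tolist()))
    truth = GroundTruth(
        kind="calibration_standards",
        seed=seed,
        params=dict(gain=gain, offset=offset, noise_sd=noise_sd, concs=concs.tolist()),
    )
    return pairs, truth
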