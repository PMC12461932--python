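"""Named experimental conditions used as generator presets.

The three conditions correspond to water-in-octanol Pickering emulsions
stabilised by positively charged nanoparticles (``NP+``), negatively
charged nanoparticles (``NP-``), and a spontaneously adsorbed lipase
layer without particles (``no-particles``).  Mean and SD values are the
published image-analysis summary statistics for these systems; the
``no-particles`` droplet diameter and bulk level are package choices (a
sessile drop has no emulsion droplet-size statistic).
"""

from __future__ import annotations

# Droplet-image generator presets: mean and SD per condition.
DROPLET_PRESETS: dict[str, dict[str, float]] = {
    "NP+": {
        "diameter_um": 5.17,
        "diameter_sd_um": 1.78,
        "peak_conc_g_per_L": 1.56,
        "peak_conc_sd_g_per_L": 0.41,
        "ring_width_um": 0.75,
        "ring_width_sd_um": 0.2,
        "bulk_conc_g_per_L": 0.098,
        "bulk_conc_sd_g_per_L": 0.09,
    },
    "NP-": {
        "diameter_um": 3.86,
        "diameter_sd_um": 1.23,
        "peak_conc_g_per_L": 1.2,
        "peak_conc_sd_g_per_L": 0.35,
        "ring_width_um": 0.51,
        "ring_width_sd_um": 0.19,
        "bulk_conc_g_per_L": 0.097,
        "bulk_conc_sd_g_per_L": 0.09,
    },
    "no-particles": {
        "diameter_um": 6.0,
        "diameter_sd_um": 1.0,
        "peak_conc_g_per_L": 1.27,
        "peak_conc_sd_g_per_L": 0.43,
        "ring_width_um": 1.48,
        "ring_width_sd_um": 0.13,
        "bulk_conc_g_per_L": 0.098,
        "bulk_conc_sd_g_per_L": 0.09,
    },
}

# Confocal pixel size (100 nm) and the reference level defining the layer
# thickness: the initial enzyme concentration of the aqueous phase.
PIXEL_SIZE_UM = 0.1
REF_CONC_G_PER_L = 0.5

# Tensiometry defaults: clean octanol/water reference IFT (midpoint of the
# 8-8.2 mN/m calibration range) and the steady-state criterion (averaged
# decline of the last 3 min below 0.005 mN/m/min).
IFT_REF_MN_PER_M = 8.1
PLATEAU_WINDOW_S = 180.0
PLATEAU_SLOPE_MN_PER_M_PER_MIN = 0.005

# Oscillatory shear protocol: time tests at 0.1 % strain and 1 rad/s;
# amplitude sweeps from 0.01 to 100 % strain at 1 rad/s.
TIME_TEST_STRAIN_PCT = 0.1
OMEGA_RAD_PER_S = 1.0
SWEEP_STRAIN_MIN_PCT = 0.01
SWEEP_STRAIN_MAX_PCT = 100.0

# Amplitude-sweep landmarks: average yield strain and the flow points of
# the enzyme-only and enzyme+particle layers.
GAMMA_Y_PCT = 1.65
GAMMA_F_ENZYME_PCT = 13.9
GAMMA_F_PARTICLES_PCT = 10.78


def droplet_preset(name: str) -> dict[str, float]:
    """Return a copy of the named droplet preset.

    Raises ``KeyError`` with the available names if ``name`` is unknown.
    """
    try:
        return dict(DROPLET_PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(DROPLET_PRESETS)}"
        ) from None
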