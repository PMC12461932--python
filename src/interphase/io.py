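"""Readers and writers for traces, sweeps, images and configuration.

All tabular artifacts are delimited UTF-8 text with a header row whose
column names carry mandatory unit suffixes (``_s``, ``_mN_per_m``,
``_pct``, ``_Pa_m``, ``_g_per_L``, ``_um``), making units
machine-checkable.  Metadata travels in leading ``#``-prefixed
``key: value`` lines.  Images are single-plane grayscale TIFF with the
physical pixel size recorded in a YAML sidecar (``<image>.meta.yaml``);
a missing pixel size is an error, never a silent assumption.
"""

from __future__ import annotations

import io as _io
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .datatypes import AmplitudeSweep, DropletImage, GroundTruth, IFTTrace, OscillationTrace
from . import presets as _presets

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "write_trace",
    "read_trace",
    "write_tiff",
    "read_tiff",
    "write_ground_truth",
    "read_ground_truth",
]

_KNOWN_SUFFIXES = ("_s", "_mN_per_m", "_pct", "_Pa_m", "_g_per_L", "_um", "_px")

_REQUIRED_COLUMNS = {
    "ift": ["time_s", "ift_mN_per_m"],
    "oscillation": ["time_s", "strain_pct", "stress_Pa_m"],
    "sweep": ["strain_pct", "gp_Pa_m", "gpp_Pa_m"],
}


@dataclass
class RunConfig:
    """Pipeline configuration with the study's protocol defaults."""

    pixel_size_um: float = _presets.PIXEL_SIZE_UM
    ref_conc_g_per_L: float = _presets.REF_CONC_G_PER_L
    plateau_window_s: float = _presets.PLATEAU_WINDOW_S
    plateau_slope_threshold: float = _presets.PLATEAU_SLOPE_MN_PER_M_PER_MIN
    yield_drop_fraction: float = 0.05
    lve_tolerance: float = 0.05
    omega_rad_per_s: float = _presets.OMEGA_RAD_PER_S
    n_angles: int = 360
    bulk_window_px: int = 10
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        for name in (
            "pixel_size_um",
            "ref_conc_g_per_L",
            "plateau_window_s",
            "plateau_slope_threshold",
            "yield_drop_fraction",
            "lve_tolerance",
            "omega_rad_per_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")


def load_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)


# ---------------------------------------------------------------- traces


def _check_columns(columns, kind: str, path) -> None:
    required = _REQUIRED_COLUMNS[kind]
    missing = [c for c in required if c not in columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in columns:
        if not col.endswith(_KNOWN_SUFFIXES):
            raise ValueError(
                f"{path}: column {col!r} has no recognised unit suffix "
                f"(expected one of {_KNOWN_SUFFIXES})"
            )


def write_trace(
    obj: IFTTrace | OscillationTrace | AmplitudeSweep, path: str | Path
) -> None:
    """Write a trace or sweep as delimited text with metadata header."""
    path = Path(path)
    meta: dict[str, object] = {}
    if isinstance(obj, IFTTrace):
        frame = pd.DataFrame(
            {"time_s": obj.time_s, "ift_mN_per_m": obj.ift_mN_per_m}
        )
        meta = {"kind": "ift", "ift_ref_mN_per_m": obj.ift_ref_mN_per_m}
        if obj.ph is not None:
            meta["ph"] = obj.ph
    elif isinstance(obj, OscillationTrace):
        frame = pd.DataFrame(
            {
                "time_s": obj.time_s,
                "strain_pct": obj.strain_pct,
                "stress_Pa_m": obj.stress_Pa_m,
            }
        )
        meta = {
            "kind": "oscillation",
            "omega_rad_per_s": obj.omega_rad_per_s,
            "timestamp_s": obj.timestamp_s,
        }
    elif isinstance(obj, AmplitudeSweep):
        frame = obj.to_frame()
        meta = {"kind": "sweep", "omega_rad_per_s": obj.omega_rad_per_s}
    else:
        raise TypeError(f"cannot serialise object of type {type(obj).__name__}")
    if obj.label:
        meta["label"] = obj.label
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, index=False, float_format="%.12g")


def read_trace(
    path: str | Path, kind: str
) -> IFTTrace | OscillationTrace | AmplitudeSweep:
    """Read a typed trace from delimited text.

    ``kind`` is one of ``ift``, ``oscillation``, ``sweep``.  Readers
    validate unit-suffixed column names and monotone time/strain axes and
    reject rather than coerce.
    """
    if kind not in _REQUIRED_COLUMNS:
        raise ValueError(f"unknown trace kind {kind!r}")
    path = Path(path)
    meta: dict[str, str] = {}
    lines = path.read_text(encoding="utf-8").splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    frame = pd.read_csv(_io.StringIO("\n".join(lines[body_start:])))
    _check_columns(list(frame.columns), kind, path)

    if kind == "ift":
        return IFTTrace(
            frame["time_s"].to_numpy(),
            frame["ift_mN_per_m"].to_numpy(),
            ift_ref_mN_per_m=float(meta.get("ift_ref_mN_per_m", _presets.IFT_REF_MN_PER_M)),
            ph=float(meta["ph"]) if "ph" in meta else None,
            label=meta.get("label", ""),
        )
    if kind == "oscillation":
        if "omega_rad_per_s" not in meta:
            raise ValueError(f"{path}: missing omega_rad_per_s metadata")
        return OscillationTrace(
            frame["time_s"].to_numpy(),
            frame["strain_pct"].to_numpy(),
            frame["stress_Pa_m"].to_numpy(),
            omega_rad_per_s=float(meta["omega_rad_per_s"]),
            timestamp_s=float(meta.get("timestamp_s", 0.0)),
            label=meta.get("label", ""),
        )
    return AmplitudeSweep(
        frame["strain_pct"].to_numpy(),
        frame["gp_Pa_m"].to_numpy(),
        frame["gpp_Pa_m"].to_numpy(),
        omega_rad_per_s=float(meta.get("omega_rad_per_s", _presets.OMEGA_RAD_PER_S)),
        label=meta.get("label", ""),
    )


# ---------------------------------------------------------------- images


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_tiff(image: DropletImage, path: str | Path) -> None:
    """Write a droplet image as 16-bit grayscale TIFF plus YAML sidecar.

    Intensities are rounded to the nearest integer count; values above
    the 16-bit range raise rather than clip silently.
    """
    path = Path(path)
    data = np.round(image.intensity)
    if data.max() > np.iinfo(np.uint16).max:
        raise ValueError("intensity exceeds the 16-bit range")
    tifffile.imwrite(path, data.astype(np.uint16))
    with open(_sidecar(path), "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {"pixel_size_um": float(image.pixel_size_um), "label": image.label}, fh
        )


def read_tiff(path: str | Path, pixel_size_um: float | None = None) -> DropletImage:
    """Read a single-plane grayscale TIFF as a droplet image.

    The physical pixel size comes from the YAML sidecar written next to
    the image, or from the ``pixel_size_um`` argument; if neither is
    available the reader raises (a pixel size is never assumed).
    Multi-channel input is rejected.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-plane grayscale image, got shape {data.shape}"
        )
    label = ""
    if pixel_size_um is None:
        sidecar = _sidecar(path)
        if not sidecar.exists():
            raise ValueError(
                f"{path}: pixel size unknown — no sidecar {sidecar.name} and no "
                "pixel_size_um given"
            )
        with open(sidecar, encoding="utf-8") as fh:
            meta = yaml.safe_load(fh) or {}
        if "pixel_size_um" not in meta:
            raise ValueError(f"{sidecar}: missing pixel_size_um")
        pixel_size_um = float(meta["pixel_size_um"])
        label = meta.get("label", "")
    return DropletImage(data.astype(float), pixel_size_um=pixel_size_um, label=label)


# ---------------------------------------------------------- ground truth


def _plain(value):
    """Convert numpy scalars/arrays to plain Python for YAML."""
    if isinstance(value, np.generic):
        return value.item()
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, dict):
        return {k: _plain(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_plain(v) for v in value]
    return value


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {"kind": truth.kind, "seed": truth.seed, "params": _plain(truth.params)},
            fh,
        )


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return GroundTruth(kind=data["kind"], seed=data["seed"], params=data["params"])
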