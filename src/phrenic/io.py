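"""File formats and configuration.

Interchange formats are deliberately plain: delimited text or flat float32
binary with a JSON sidecar for recordings and traces, TIFF with a JSON
sidecar for images, CSV for tables, YAML for configuration.  Mandatory
metadata (sampling rate, pixel size) is never guessed; a missing sidecar or
key is a hard error.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .bursts import NerveRecording
from .breathing import BreathTrace
from .dendrites import DendriteImage
from .puncta import SomaOutline
from .topography import SomaMap

__all__ = [
    "read_recording",
    "write_recording",
    "read_breath_trace",
    "write_breath_trace",
    "read_image",
    "write_image",
    "read_dendrite_image",
    "read_soma_maps",
    "write_soma_map",
    "read_soma_outlines",
    "read_table",
    "write_table",
    "load_config",
    "ConfigError",
]

_BINARY_SUFFIXES = {".f32", ".bin", ".raw", ".dat"}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _load_sidecar(path: Path, required: tuple[str, ...]) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing JSON sidecar {sidecar} (required keys: {required})"
        )
    meta = json.loads(sidecar.read_text())
    for key in required:
        if key not in meta:
            raise KeyError(f"sidecar {sidecar} missing required key {key!r}")
    return meta


# ---------------------------------------------------------------------------
# recordings and traces


def read_recording(path: str | Path) -> NerveRecording:
    """Read a nerve recording from delimited text or float32 binary.

    Text format: two columns (time_s, value), any common delimiter,
    optional header; the sampling rate comes from the time column.  Binary
    format: flat little-endian float32 samples with a JSON sidecar
    ``<name>.<ext>.json`` carrying at least ``sampling_rate_hz``.
    """
    path = Path(path)
    if path.suffix.lower() in _BINARY_SUFFIXES:
        meta = _load_sidecar(path, ("sampling_rate_hz",))
        samples = np.fromfile(path, dtype="<f4").astype(float)
        return NerveRecording(samples, float(meta["sampling_rate_hz"]),
                              float(meta.get("start_time_s", 0.0)),
                              meta.get("source_id", path.stem))
    table = pd.read_csv(path, sep=None, engine="python", comment="#",
                        skip_blank_lines=True)
    if table.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time_s, value)")
    t = table.iloc[:, 0].to_numpy(dtype=float)
    v = table.iloc[:, 1].to_numpy(dtype=float)
    dt = np.diff(t)
    if dt.size == 0 or np.any(dt <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    fs = 1.0 / float(np.median(dt))
    return NerveRecording(v, fs, float(t[0]), path.stem)


def write_recording(rec: NerveRecording, path: str | Path,
                    fmt: str = "text") -> Path:
    """Write a recording as text (time_s, value) or float32 binary + sidecar."""
    path = Path(path)
    if fmt == "binary":
        rec.samples.astype("<f4").tofile(path)
        _sidecar_path(path).write_text(json.dumps({
            "sampling_rate_hz": rec.sampling_rate_hz,
            "start_time_s": rec.start_time_s,
            "source_id": rec.source_id,
            "dtype": "float32",
        }, indent=1))
    elif fmt == "text":
        out = pd.DataFrame({"time_s": rec.times_s, "value": rec.samples})
        out.to_csv(path, index=False, float_format="%.9g")
    else:
        raise ValueError("fmt must be 'text' or 'binary'")
    return path


def read_breath_trace(path: str | Path, condition: str = "room_air",
                      subject: str = "", day: int = 0) -> BreathTrace:
    """Read a (time_s, volume) delimited text trace."""
    rec = read_recording(path)
    return BreathTrace(rec.samples, rec.sampling_rate_hz, condition=condition,
                       subject=subject, day=day)


def write_breath_trace(trace: BreathTrace, path: str | Path) -> Path:
    t = np.arange(trace.volume.size) / trace.sampling_rate_hz
    pd.DataFrame({"time_s": t, "volume": trace.volume}).to_csv(
        path, index=False, float_format="%.9g")
    return Path(path)


# ---------------------------------------------------------------------------
# images


def read_image(path: str | Path, require: tuple[str, ...] = ("pixel_size_um",)
               ) -> tuple[np.ndarray, dict]:
    """Read a TIFF plus its JSON sidecar metadata (pixel size mandatory)."""
    path = Path(path)
    meta = _load_sidecar(path, require)
    return np.asarray(tifffile.imread(path), dtype=float), meta


def write_image(image: np.ndarray, path: str | Path, meta: dict) -> Path:
    """Write a TIFF and its JSON sidecar; ``pixel_size_um`` is mandatory."""
    if "pixel_size_um" not in meta:
        raise KeyError("image metadata must include pixel_size_um")
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_dendrite_image(path: str | Path) -> DendriteImage:
    """Read a dendrite image; the sidecar must give pixel size, soma centroid
    (row, col) and midline column."""
    arr, meta = read_image(
        path, require=("pixel_size_um", "soma_centroid", "midline_col"))
    return DendriteImage(arr, float(meta["pixel_size_um"]),
                         tuple(meta["soma_centroid"]), float(meta["midline_col"]))


# ---------------------------------------------------------------------------
# tables


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python",
                       skipinitialspace=True)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    df.to_csv(path, index=False)
    return Path(path)


def read_soma_maps(path: str | Path) -> list[SomaMap]:
    """Read soma maps from CSV (x_um, y_um[, radius_um][, section]).

    Returns one map per section, in order of first appearance; without a
    section column the whole file is one map.
    """
    df = read_table(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "x_um" not in cols or "y_um" not in cols:
        raise ValueError(f"{path}: need x_um and y_um columns")
    if "section" in cols:
        groups = df.groupby(df[cols["section"]], sort=False)
    else:
        groups = [("all", df)]
    maps = []
    for name, g in groups:
        radius = (g[cols["radius_um"]].to_numpy(dtype=float)
                  if "radius_um" in cols else 5.0)
        maps.append(SomaMap(g[cols["x_um"]].to_numpy(dtype=float),
                            g[cols["y_um"]].to_numpy(dtype=float),
                            radius, section_id=str(name)))
    return maps


def write_soma_map(soma_map: SomaMap, path: str | Path) -> Path:
    df = pd.DataFrame({
        "soma_id": np.arange(soma_map.n),
        "x_um": soma_map.x_um,
        "y_um": soma_map.y_um,
        "radius_um": soma_map.radius_um,
        "section": soma_map.section_id or "all",
    })
    return write_table(df, path)


def read_soma_outlines(path: str | Path) -> list[SomaOutline]:
    """Read soma outline polygons from CSV (soma_id, x_um, y_um vertices)."""
    df = read_table(path)
    cols = {c.strip().lower(): c for c in df.columns}
    for need in ("soma_id", "x_um", "y_um"):
        if need not in cols:
            raise ValueError(f"{path}: need soma_id, x_um, y_um columns")
    outlines = []
    for soma_id, g in df.groupby(df[cols["soma_id"]], sort=False):
        verts = np.column_stack([g[cols["x_um"]], g[cols["y_um"]]])
        outlines.append(SomaOutline(verts, soma_id=str(soma_id)))
    return outlines


# ---------------------------------------------------------------------------
# configuration


class ConfigError(ValueError):
    pass


KNOWN_CONFIG_KEYS: dict[str, set[str] | None] = {
    "seed": None,
    "out_dir": None,
    "log_level": None,
    "stages": None,
    "nerve": {
        "conditions", "n_units", "burst_rate_per_min", "burst_duration_s",
        "sync_freq_hz", "phase_jitter_ms", "lock_probability",
        "background_rate_hz", "condition", "unit_rate_hz", "duration_s",
        "sampling_rate_hz", "noise_sd", "spike_amplitude", "spike_width_ms",
        "n_bursts", "split_hz",
    },
    "somata": {"conditions", "n", "radius_um", "field_um", "margin_um",
               "tol_um", "shape", "alpha_um"},
    "dendrites": {"conditions", "contralateral_extent_um", "pixel_size_um",
                  "span_um", "ray_sigma_um"},
    "puncta": {"conditions", "n_somata", "paired_per_soma",
               "distractor_density_per_um2", "apposition_sep_um", "field_um",
               "max_sep_um", "shell_um"},
    "breath": {"conditions", "tidal_volume", "breaths_per_min", "noise_sd",
               "duration_s", "window_s", "n_days"},
}


def validate_config(config: dict) -> dict:
    """Reject unknown keys anywhere in the configuration."""
    for key, value in config.items():
        if key not in KNOWN_CONFIG_KEYS:
            raise ConfigError(f"unknown configuration key {key!r}")
        allowed = KNOWN_CONFIG_KEYS[key]
        if allowed is not None:
            if not isinstance(value, dict):
                raise ConfigError(f"configuration block {key!r} must be a mapping")
            unknown = set(value) - allowed
            if unknown:
                raise ConfigError(
                    f"unknown keys in block {key!r}: {sorted(unknown)}"
                )
    return config


def load_config(path: str | Path) -> dict:
    """Load and validate a YAML configuration file."""
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ConfigError("configuration root must be a mapping")
    return validate_config(config)
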