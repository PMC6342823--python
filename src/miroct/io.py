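"""Configuration files, frame/scan/domain I/O, and image export.

Units policy (stated in every header this module writes): lengths in µm,
wavelengths in nm, time in fs/ps, mua/mus in mm^-1.  Depth axes are always
one-way OPD in air.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .forward_model import RawFrame

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "default_config",
    "export_image",
    "import_image",
    "save_frame_csv",
    "load_frame_csv",
    "save_ascan_csv",
    "save_domain",
    "load_domain",
]


class ConfigError(ValueError):
    """Configuration schema violation; the message names the offending key."""


DEFAULTS: dict = {
    "seed": 0,
    "verbosity": 1,
    "upconversion": {
        "pump_nm": 1064.0,
        "band_nm": [3576.0, 4625.0],
        "qe": 0.01,
        "poling_um": 23.0,
    },
    "source": {
        "shape": "flat",
    },
    "spectrometer": {
        "n_pixels": 4096,
        "lambda_range_nm": [796.0, 879.0],
        "resolution_fwhm_nm": 2.7,
        "bit_depth": 10,
        "line_rate_hz": 45000.0,
        "nonlinearity": [0.0, 0.0],
        "n_detected_pixels": 2286,
    },
    "phantom": {
        "kind": "mirror",          # mirror | ceramic | wafer
        "mirror_opd_um": 100.0,
        "mirror_r": 0.05,
    },
    "scan": {
        "speed_mm_s": 3.0,
        "integration_ms": 3.0,
        "step_um": 10.0,
        "calibration_opds_um": [300.0, 900.0],
        "rolloff_probes_um": [100.0, 340.0, 580.0, 820.0, 1060.0, 1300.0,
                              1540.0, 1780.0, 2020.0, 2260.0, 2500.0],
        "zero_pad_factor": 4,
        "window": "hanning",
    },
    "mc": {
        "wavelength_tag": "4.0",
        "na": 0.1,
        "photons_per_line": 10000,
        "beam_width_um": 15.0,
        "lateral_step_um": 10.0,
        "t_total_ps": 14.4,
        "dt_fs": 24.0,
    },
    "output": {
        "dynamic_range_db": 40.0,
        "format": "tiff",
    },
}

_SCHEMA_TYPES = {
    "seed": int,
    "verbosity": int,
    "upconversion.pump_nm": (int, float),
    "upconversion.band_nm": list,
    "upconversion.qe": (int, float),
    "upconversion.poling_um": (int, float),
    "spectrometer.n_pixels": int,
    "spectrometer.bit_depth": int,
    "spectrometer.resolution_fwhm_nm": (int, float),
    "scan.zero_pad_factor": int,
    "mc.photons_per_line": int,
}


def _merge(base: dict, override: dict, path="") -> dict:
    out = dict(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{here} must be a table/mapping")
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


def _validate(cfg: dict) -> None:
    for dotted, types in _SCHEMA_TYPES.items():
        node = cfg
        for part in dotted.split("."):
            node = node[part]
        if not isinstance(node, types) or isinstance(node, bool):
            raise ConfigError(f"{dotted} has the wrong type "
                              f"({type(node).__name__})")
    band = cfg["upconversion"]["band_nm"]
    if len(band) != 2 or not band[0] < band[1]:
        raise ConfigError("upconversion.band_nm must be [min, max] with min < max")
    kind = cfg["phantom"]["kind"]
    if kind not in ("mirror", "ceramic", "wafer"):
        raise ConfigError(f"phantom.kind must be mirror|ceramic|wafer, got {kind!r}")
    if kind == "wafer" and "n_group" not in cfg["phantom"]:
        raise ConfigError("missing required key: phantom.n_group "
                          "(silicon group index must be supplied)")
    opds = cfg["scan"]["calibration_opds_um"]
    if len(opds) != 2 or opds[0] == opds[1]:
        raise ConfigError("scan.calibration_opds_um must be two distinct OPDs")


def default_config() -> dict:
    import copy
    return copy.deepcopy(DEFAULTS)


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load, merge over defaults, and validate a TOML (or YAML) config."""
    cfg = default_config()
    if path is not None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml
            with open(path) as fh:
                user = yaml.safe_load(fh) or {}
        else:
            with open(path, "rb") as fh:
                user = tomllib.load(fh)
        # phantom.n_group is optional in DEFAULTS but allowed in user config
        phantom = user.get("phantom", {})
        n_group = phantom.pop("n_group", None)
        cfg = _merge(cfg, user)
        if n_group is not None:
            cfg["phantom"]["n_group"] = n_group
    if overrides:
        for dotted, value in overrides.items():
            node = cfg
            parts = dotted.split(".")
            for part in parts[:-1]:
                if part not in node:
                    raise ConfigError(f"unknown configuration key: {dotted}")
                node = node[part]
            node[parts[-1]] = value
    _validate(cfg)
    return cfg


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration with per-stage seeds derived from the global one."""

    cfg: dict
    seeds: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path=None, overrides=None) -> "RunConfig":
        cfg = load_config(path, overrides)
        root = np.random.SeedSequence(int(cfg["seed"]))
        children = root.spawn(4)
        seeds = {name: int(child.generate_state(1)[0] & 0x7FFFFFFF)
                 for name, child in zip(
                     ("frames", "mc", "noise", "misc"), children)}
        return cls(cfg=cfg, seeds=seeds)

    def __getitem__(self, key):
        return self.cfg[key]


# --------------------------------------------------------------------------
# frame / scan / domain I/O
# --------------------------------------------------------------------------

_CSV_HEADER = ("# miroct raw frame; units: counts per pixel\n"
               "# kind={kind} integration_ms={integration} bit_depth={bits} "
               "seed={seed}\npixel,counts\n")


def save_frame_csv(frame: RawFrame, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_CSV_HEADER.format(kind=frame.kind,
                                    integration=frame.integration_ms,
                                    bits=frame.bit_depth, seed=frame.seed))
        for i, c in enumerate(frame.counts):
            fh.write(f"{i},{int(c)}\n")


def load_frame_csv(path) -> RawFrame:
    path = Path(path)
    meta = {}
    counts = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                for token in line[1:].split():
                    if "=" in token:
                        key, _, value = token.partition("=")
                        meta[key] = value
            elif line.strip() and not line.startswith("pixel"):
                counts.append(int(line.strip().split(",")[1]))
    seed = meta.get("seed")
    return RawFrame(counts=np.asarray(counts, dtype=np.int64),
                    kind=meta.get("kind", "sample"),
                    integration_ms=float(meta.get("integration_ms", 0.0)),
                    bit_depth=int(meta.get("bit_depth", 10)),
                    seed=None if seed in (None, "None") else int(seed))


def save_ascan_csv(ascan, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# miroct A-scan; depth is one-way OPD in air (µm)\n")
        fh.write("depth_um,magnitude,db\n")
        for z, m, d in zip(ascan.depth_um, ascan.magnitude, ascan.db):
            fh.write(f"{z:.6g},{m:.8g},{d:.4f}\n")


def save_domain(path, domain) -> None:
    """Binary voxel container (.npz) plus a JSON sidecar."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), mua=domain.mua,
                        mus=domain.mus, g=domain.g, n=domain.n)
    sidecar = {
        "dims": list(domain.dims),
        "voxel_size_um": domain.voxel_size_um,
        "units": {"mua": "mm^-1", "mus": "mm^-1", "length": "um"},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_domain(path):
    from .mc_transport import VoxelDomain
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    data = np.load(path.with_suffix(".npz"))
    return VoxelDomain(mua=data["mua"], mus=data["mus"], g=data["g"],
                       n=data["n"], voxel_size_um=sidecar["voxel_size_um"])


# --------------------------------------------------------------------------
# image export
# --------------------------------------------------------------------------

def _scan_db_image(scan) -> np.ndarray:
    if hasattr(scan, "db"):
        return np.asarray(scan.db, dtype=float)
    image = np.asarray(scan.image, dtype=float)
    floor = np.median(image[image > 0]) if np.any(image > 0) else 1.0
    return 20.0 * np.log10(np.maximum(image, np.finfo(float).tiny) / floor)


def export_image(scan, path, dynamic_range_db: float = 40.0,
                 fmt: str = "tiff") -> Path:
    """Write a B-scan as 16-bit grayscale (row = depth, column = lateral).

    dB values in ``[max - dynamic_range_db, max]`` map linearly onto the
    16-bit code range; a JSON sidecar records both axes and the mapping so
    dB values can be recovered on import.
    """
    if fmt not in ("tiff", "png"):
        raise ValueError(f"unknown image format {fmt!r}")
    db = _scan_db_image(scan)
    if db.ndim != 2 or db.size == 0:
        raise ValueError("scan must carry a non-empty 2-D image")
    top = float(db.max())
    lo = top - float(dynamic_range_db)
    norm = np.clip((db - lo) / (top - lo), 0.0, 1.0)
    img = np.round(norm * 65535.0).astype(np.uint16)
    path = Path(path)
    if fmt == "tiff":
        import tifffile
        tifffile.imwrite(path, img)
    else:
        import imageio.v3 as iio
        iio.imwrite(path, img, extension=".png")
    sidecar = {
        "db_max": top,
        "db_min": lo,
        "dynamic_range_db": float(dynamic_range_db),
        "rows": "depth (one-way OPD in air, µm)",
        "cols": "lateral (µm)",
        "depth_um": np.asarray(scan.depth_um, dtype=float).tolist(),
        "lateral_um": np.asarray(scan.lateral_um, dtype=float).tolist(),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar))
    return path


def import_image(path):
    """Round-trip helper: read an exported image back as a dB array."""
    path = Path(path)
    sidecar = json.loads(
        path.with_suffix(path.suffix + ".json").read_text())
    if path.suffix == ".tiff" or path.suffix == ".tif":
        import tifffile
        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio
        img = iio.imread(path)
    norm = img.astype(float) / 65535.0
    return sidecar["db_min"] + norm * (sidecar["db_max"] - sidecar["db_min"])
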