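"""Readers, writers, and configuration loading.

Single images: PNG (8/16-bit, values mapped to/from [0, 1]) and TIFF (float
preserved, integers mapped like PNG).  Stacks: NPZ (lossless) or multi-page
TIFF with the acquisition geometry stored as JSON in the image description.
Configs: YAML (JSON is a YAML subset, so both parse); unknown keys are errors
so hyperparameter typos fail fast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .network import NetworkConfig
from .optics import LRStack, OpticsGeometry
from .synth import DatasetManifest
from .training import TrainConfig

__all__ = [
    "FormatError",
    "ConfigError",
    "RunConfig",
    "read_image",
    "write_image",
    "read_stack",
    "write_stack",
    "load_config",
]


class FormatError(ValueError):
    """Unsupported or malformed image/stack file."""


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

def _to_unit(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    return arr.astype(np.float64)


def read_image(path: str | Path, channels: int | None = None) -> np.ndarray:
    """Read PNG/TIFF into float64 values in [0, 1] (integer formats rescaled).

    ``channels`` asserts the leading channel count; a mismatch (e.g. an RGB
    PNG read where a 2-channel sample is expected) raises FormatError.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = iio.imread(path)
        if arr.ndim == 3:  # imageio returns HWC; use channel-first like the rest
            arr = np.moveaxis(arr, -1, 0)
    else:
        raise FormatError(f"unsupported image format: {path}")
    arr = _to_unit(np.asarray(arr))
    if channels is not None:
        have = arr.shape[0] if arr.ndim == 3 else 1
        if have != channels:
            raise FormatError(
                f"{path}: expected {channels} channel(s), found {have}"
            )
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write an image; PNG is quantized to 16 bits, TIFF keeps float32."""
    path = Path(path)
    image = np.asarray(image)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, image.astype(np.float32))
    elif suffix == ".png":
        arr = np.clip(image, 0.0, 1.0)
        if arr.ndim == 3:
            # multi-channel PNG is 8-bit (16-bit PNG is grayscale only)
            arr = np.moveaxis(arr, 0, -1)
            iio.imwrite(path, (arr * 255.0 + 0.5).astype(np.uint8))
        else:
            iio.imwrite(path, (arr * 65535.0 + 0.5).astype(np.uint16))
    else:
        raise FormatError(f"unsupported image format: {path}")


# ---------------------------------------------------------------------------
# Stacks
# ---------------------------------------------------------------------------

def write_stack(path: str | Path, stack: LRStack) -> None:
    """Persist an LRStack as NPZ (.npz) or multi-page TIFF (.tif/.tiff)."""
    path = Path(path)
    rows = np.array([r for r, _ in stack.led_indices], dtype=np.int64)
    cols = np.array([c for _, c in stack.led_indices], dtype=np.int64)
    if path.suffix.lower() == ".npz":
        np.savez(
            path,
            images=stack.images,
            led_rows=rows,
            led_cols=cols,
            noise_sigma=np.float64(stack.noise_sigma),
            **{f"geometry_{k}": v for k, v in stack.geometry.to_dict().items()},
        )
    elif path.suffix.lower() in (".tif", ".tiff"):
        meta = {
            "geometry": stack.geometry.to_dict(),
            "noise_sigma": stack.noise_sigma,
            "led_rows": rows.tolist(),
            "led_cols": cols.tolist(),
        }
        tifffile.imwrite(
            path, stack.images.astype(np.float32), description=json.dumps(meta)
        )
    else:
        raise FormatError(f"unsupported stack format: {path}")


def read_stack(path: str | Path) -> LRStack:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.suffix.lower() == ".npz":
        try:
            with np.load(path) as z:
                geom = OpticsGeometry(
                    **{
                        k[len("geometry_") :]: (
                            int(z[k]) if k.endswith(("grid", "factor", "size")) else float(z[k])
                        )
                        for k in z.files
                        if k.startswith("geometry_")
                    }
                )
                leds = list(zip(z["led_rows"].tolist(), z["led_cols"].tolist()))
                return LRStack(z["images"], leds, geom, float(z["noise_sigma"]))
        except (KeyError, ValueError) as exc:
            raise FormatError(f"corrupt stack file {path}: {exc}") from exc
    if path.suffix.lower() in (".tif", ".tiff"):
        try:
            with tifffile.TiffFile(path) as tf:
                meta = json.loads(tf.pages[0].description)
                images = tf.asarray().astype(np.float64)
            geom = OpticsGeometry(**meta["geometry"])
            leds = list(zip(meta["led_rows"], meta["led_cols"]))
            return LRStack(images, leds, geom, float(meta["noise_sigma"]))
        except (KeyError, ValueError, json.JSONDecodeError) as exc:
            raise FormatError(f"corrupt stack file {path}: {exc}") from exc
    raise FormatError(f"unsupported stack format: {path}")


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated nested configuration for a pipeline run."""

    optics: OpticsGeometry
    dataset: DatasetManifest
    network: NetworkConfig
    train: TrainConfig
    verbosity: int = 1


_SECTION_TYPES = {
    "optics": OpticsGeometry,
    "dataset": DatasetManifest,
    "network": NetworkConfig,
    "train": TrainConfig,
}


def _build_section(name: str, cls, payload: dict, optics: OpticsGeometry | None):
    import dataclasses as dc

    known = {f.name for f in dc.fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in section '{name}': {sorted(unknown)}")
    kwargs = dict(payload)
    for key in ("sa_dilations", "split", "styles"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    if cls is DatasetManifest and optics is not None and "geometry" not in kwargs:
        kwargs["geometry"] = optics
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section '{name}': {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON run config; unknown sections or keys are errors."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - set(_SECTION_TYPES) - {"verbosity"}
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    optics = _build_section("optics", OpticsGeometry, raw.get("optics", {}), None)
    return RunConfig(
        optics=optics,
        dataset=_build_section("dataset", DatasetManifest, raw.get("dataset", {}), optics),
        network=_build_section("network", NetworkConfig, raw.get("network", {}), None),
        train=_build_section("train", TrainConfig, raw.get("train", {}), None),
        verbosity=int(raw.get("verbosity", 1)),
    )
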