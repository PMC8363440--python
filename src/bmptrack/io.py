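"""File formats and run configuration.

Sequences are read from multi-frame TIFF files or directories of
lexicographically ordered PNG frames, always as grayscale; integer images
are rescaled to [0, 1].  Physical pixel spacing comes from a YAML sidecar
(``<stem>.yaml`` next to a TIFF, ``sequence.yaml`` inside a PNG directory)
when present, else from the caller, else from the package default of
0.92 mm/px.

``RunConfig`` is the validated YAML-backed configuration of a tracking run;
validation errors name the offending key so misconfigured runs fail before
any computation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .phantom import PhantomConfig
from .tracking import DEFAULT_PIXEL_SPACING_MM, ImageSequence

__all__ = [
    "SequenceReadError",
    "ConfigError",
    "RunConfig",
    "read_sequence",
    "read_seeds_csv",
    "config_hash",
    "provenance_lines",
]

logger = logging.getLogger("bmptrack")

_PNG_SIDECAR = "sequence.yaml"


class SequenceReadError(IOError):
    pass


class ConfigError(ValueError):
    pass


def _to_gray01(arr: np.ndarray, name: str) -> np.ndarray:
    scale = (
        float(np.iinfo(arr.dtype).max)
        if np.issubdtype(arr.dtype, np.integer)
        else None
    )
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise SequenceReadError(
            f"{name}: expected a 2-D grayscale image, got shape {arr.shape}"
        )
    arr = arr.astype(np.float64)
    if scale is not None:
        arr /= scale
    return arr


def _sidecar_spacing(path: Path) -> float | None:
    if not path.is_file():
        return None
    data = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    v = data.get("pixel_spacing_mm")
    return float(v) if v is not None else None


def read_sequence(
    path: str | Path,
    pixel_spacing_mm: float | None = None,
) -> ImageSequence:
    """Load a multi-frame TIFF or a directory of PNG frames as a sequence.

    Sidecar YAML spacing wins over the ``pixel_spacing_mm`` argument, which
    wins over the 0.92 mm/px default.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.png"))
        if not files:
            raise SequenceReadError(f"{path}: no PNG frames found")
        frames = []
        shape = None
        for f in files:
            try:
                arr = _to_gray01(np.asarray(iio.imread(f)), f.name)
            except SequenceReadError:
                raise
            except Exception as exc:  # unreadable file: name it
                raise SequenceReadError(f"{f}: {exc}") from exc
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise SequenceReadError(
                    f"{f.name}: frame shape {arr.shape} differs from {shape}"
                )
            frames.append(arr)
        stack = np.stack(frames)
        sidecar = _sidecar_spacing(path / _PNG_SIDECAR)
    elif path.is_file():
        try:
            raw = tifffile.imread(path)
        except Exception as exc:
            raise SequenceReadError(f"{path}: {exc}") from exc
        if raw.ndim == 2:
            raw = raw[None]
        if raw.ndim != 3:
            raise SequenceReadError(f"{path}: expected a grayscale stack, got shape {raw.shape}")
        stack = raw.astype(np.float64)
        if np.issubdtype(raw.dtype, np.integer):
            stack /= float(np.iinfo(raw.dtype).max)
        sidecar = _sidecar_spacing(path.with_suffix(".yaml"))
    else:
        raise SequenceReadError(f"{path}: no such file or directory")

    spacing = sidecar if sidecar is not None else (
        pixel_spacing_mm if pixel_spacing_mm is not None else DEFAULT_PIXEL_SPACING_MM
    )
    seq = ImageSequence(stack, spacing)
    logger.info(
        "loaded %d frames of %dx%d px at %.3f mm/px from %s",
        seq.n_frames, seq.frame_shape[0], seq.frame_shape[1], spacing, path,
    )
    return seq


def read_seeds_csv(path: str | Path) -> list:
    """Read spot seeds from CSV with columns spot_id, row, col."""
    from .tracking import SpotSeed
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    for c in ("spot_id", "row", "col"):
        if c not in df.columns:
            raise ConfigError(f"{path}: missing column {c!r}")
    return [
        SpotSeed(str(r.spot_id), (int(r.row), int(r.col)))
        for r in df.itertuples(index=False)
    ]


# --- run configuration -------------------------------------------------------

_POW2 = {2 ** k for k in range(0, 9)}

# key -> (type coercion, predicate, human-readable constraint)
_SCHEMA = {
    "method": (str, lambda v: v in ("global", "bmp", "log"), "one of global|bmp|log"),
    "block_side": (int, lambda v: v in _POW2, "a power of two <= 256"),
    "window_radius": (int, lambda v: v >= 0, ">= 0"),
    "pixel_spacing_mm": (float, lambda v: v > 0, "> 0"),
    "template_update": (str, lambda v: v in ("previous", "first"), "previous|first"),
    "seed": (int, lambda v: 0 <= v < 2 ** 31, "in [0, 2^31)"),
    "verbosity": (int, lambda v: 0 <= v <= 2, "0, 1 or 2"),
}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a tracking/benchmark run."""

    method: str = "bmp"
    block_side: int = 16
    window_radius: int = 4
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM
    template_update: str = "previous"
    seed: int = 0
    verbosity: int = 1
    phantom: PhantomConfig = field(default_factory=PhantomConfig)

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        """Build from a plain mapping, validating every key.

        Unknown keys and constraint violations raise :class:`ConfigError`
        naming the offending key path.
        """
        data = dict(data or {})
        kwargs = {}
        phantom_data = data.pop("phantom", None)
        for key, value in data.items():
            if key not in _SCHEMA:
                raise ConfigError(f"unknown configuration key: {key}")
            coerce, pred, constraint = _SCHEMA[key]
            try:
                value = coerce(value)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"{key}: not a valid {coerce.__name__}") from exc
            if not pred(value):
                raise ConfigError(f"{key}: must be {constraint} (got {value!r})")
            kwargs[key] = value
        if phantom_data is not None:
            valid = {f for f in PhantomConfig.__dataclass_fields__}
            for k in phantom_data:
                if k not in valid:
                    raise ConfigError(f"phantom.{k}: unknown configuration key")
            try:
                pc = PhantomConfig(**phantom_data)
                pc.validate()
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"phantom: {exc}") from exc
            kwargs["phantom"] = pc
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def config_hash(obj) -> str:
    """Short stable hash of a configuration-like object (dataclass or dict)."""
    if hasattr(obj, "__dataclass_fields__"):
        obj = asdict(obj)
    payload = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def provenance_lines(config_obj, seed: int | None = None) -> list[str]:
    """Header lines recording tool version, config hash and seed."""
    from . import __version__

    lines = [f"bmptrack {__version__}", f"config_hash {config_hash(config_obj)}"]
    if seed is not None:
        lines.append(f"seed {seed}")
    return lines
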