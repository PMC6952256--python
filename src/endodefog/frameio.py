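"""Frame and configuration I/O.

Single frames are read and written as PNG or TIFF (8- or 16-bit) through
imageio; sequences are numbered-frame directories sorted by filename.
Transmission maps are stored as 16-bit grayscale PNG to preserve
precision.  Configurations serialise to YAML or JSON by file extension.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .frames import to_uint8
from .pipeline import PipelineConfig

__all__ = [
    "read_frame",
    "write_frame",
    "read_sequence",
    "write_transmission",
    "read_transmission",
    "load_config",
    "save_config",
]

FRAME_EXTENSIONS = (".png", ".tif", ".tiff")


def read_frame(path) -> np.ndarray:
    """Load an image file as a unit-interval RGB array.

    Grayscale inputs are replicated to three channels; alpha is dropped;
    8- and 16-bit integer depths are rescaled by their full range.
    """
    img = iio.imread(Path(path))
    if img.dtype == np.uint8:
        arr = img.astype(np.float64) / 255.0
    elif img.dtype == np.uint16:
        arr = img.astype(np.float64) / 65535.0
    elif np.issubdtype(img.dtype, np.floating):
        arr = np.clip(img.astype(np.float64), 0.0, 1.0)
    else:
        raise ValueError(f"unsupported image dtype {img.dtype} in {path}")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"cannot interpret {path} as an RGB frame: shape {arr.shape}")
    return arr


def write_frame(path, frame: np.ndarray) -> None:
    """Write a unit-interval RGB frame as an 8-bit image."""
    iio.imwrite(Path(path), to_uint8(frame))


def write_transmission(path, transmission: np.ndarray) -> None:
    """Write a transmission map as 16-bit grayscale PNG."""
    arr = np.clip(np.asarray(transmission), 0.0, 1.0)
    iio.imwrite(Path(path), np.rint(arr * 65535.0).astype(np.uint16))


def read_transmission(path) -> np.ndarray:
    img = iio.imread(Path(path))
    return img.astype(np.float64) / np.iinfo(img.dtype).max


def read_sequence(directory, pattern: str = "*") -> tuple:
    """Read all frames in a directory, sorted by filename.

    Returns ``(frames, paths)``; unreadable files are skipped with a
    warning recorded via the logging module.
    """
    import logging

    directory = Path(directory)
    paths = sorted(
        p
        for p in directory.glob(pattern)
        if p.suffix.lower() in FRAME_EXTENSIONS
    )
    frames, kept = [], []
    for p in paths:
        try:
            frames.append(read_frame(p))
            kept.append(p)
        except Exception as exc:  # plugin backends raise assorted types
            logging.getLogger(__name__).warning("skipping unreadable frame %s: %s", p, exc)
    return frames, kept


def load_config(path) -> PipelineConfig:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return PipelineConfig.from_dict(data or {})


def save_config(path, cfg: PipelineConfig) -> None:
    path = Path(path)
    data = cfg.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
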