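"""Core image representation and colour primitives.

All pipeline stages operate on floating-point RGB rasters of shape
``(height, width, 3)`` with channel values on the unit interval.  8-bit
integer images are mapped to that representation at the I/O boundary and
back with :func:`from_uint8` / :func:`to_uint8`, which round-trip all 256
levels exactly.

Luma follows the Rec. 601 weighting H = a*R + b*G + c*B with
a=0.299, b=0.587, c=0.114; the YCbCr conversions use the matching BT.601
matrices.  The *studio* convention (8-bit luma spanning 16-235, chroma
16-240) is the package default because the blending stage expresses its
weight intervals and stretch bounds in studio-range 8-bit luma units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LumaCoefficients",
    "REC601_LUMA",
    "YCbCrFrame",
    "validate_frame",
    "from_uint8",
    "to_uint8",
    "luminance",
    "mean_luminance",
    "rgb_to_ycbcr",
    "ycbcr_to_rgb",
]


@dataclass(frozen=True)
class LumaCoefficients:
    """Channel weights of the luma formula H = a*R + b*G + c*B.

    The defaults are the Rec. 601 weights; the three coefficients must sum
    to one so that achromatic pixels keep their gray level.
    """

    a: float = 0.299
    b: float = 0.587
    c: float = 0.114

    def __post_init__(self) -> None:
        if abs(self.a + self.b + self.c - 1.0) > 1e-9:
            raise ValueError(
                f"luma coefficients must sum to 1, got {self.a + self.b + self.c!r}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c], dtype=np.float64)


REC601_LUMA = LumaCoefficients()

# BT.601 8-bit studio-range encoding matrix: Y' spans [16, 235], Cb/Cr span
# [16, 240] with neutral chroma at 128 (all on the 0-255 scale; this module
# keeps everything divided by 255).
_STUDIO_MATRIX = np.array(
    [
        [65.481, 128.553, 24.966],
        [-37.797, -74.203, 112.0],
        [112.0, -93.786, -18.214],
    ]
) / 255.0
_STUDIO_OFFSET = np.array([16.0, 128.0, 128.0]) / 255.0

# Full-range JPEG-style variant: Y' spans [0, 1], chroma centred at 0.5.
_FULL_MATRIX = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168736, -0.331264, 0.5],
        [0.5, -0.418688, -0.081312],
    ]
)
_FULL_OFFSET = np.array([0.0, 0.5, 0.5])

_CONVENTIONS = {
    "studio": (_STUDIO_MATRIX, _STUDIO_OFFSET),
    "full": (_FULL_MATRIX, _FULL_OFFSET),
}


@dataclass
class YCbCrFrame:
    """Luma/chroma planes of one frame plus the range convention used."""

    y: np.ndarray
    cb: np.ndarray
    cr: np.ndarray
    range_convention: str = "studio"

    def __post_init__(self) -> None:
        if self.range_convention not in _CONVENTIONS:
            raise ValueError(f"unknown range convention {self.range_convention!r}")
        if not (self.y.shape == self.cb.shape == self.cr.shape):
            raise ValueError("Y, Cb and Cr planes must share dimensions")

    @property
    def shape(self) -> tuple:
        return self.y.shape


def validate_frame(frame: np.ndarray, name: str = "frame") -> np.ndarray:
    """Check an RGB raster and return it as float64 on [0, 1]."""
    arr = np.asarray(frame, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{name} must have shape (height, width, 3), got {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"{name} must contain at least one pixel")
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains non-finite pixel values")
    if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
        raise ValueError(f"{name} values must lie in [0, 1]")
    return np.clip(arr, 0.0, 1.0)


def from_uint8(img: np.ndarray) -> np.ndarray:
    """Map an 8-bit image to the unit interval."""
    img = np.asarray(img)
    if img.dtype != np.uint8:
        raise ValueError(f"expected uint8 input, got {img.dtype}")
    return img.astype(np.float64) / 255.0


def to_uint8(frame: np.ndarray) -> np.ndarray:
    """Quantize a unit-interval image to 8 bits (round-to-nearest)."""
    return np.clip(np.rint(np.asarray(frame) * 255.0), 0, 255).astype(np.uint8)


def luminance(frame: np.ndarray, coeffs: LumaCoefficients = REC601_LUMA) -> np.ndarray:
    """Per-pixel luma H = a*R + b*G + c*B of an RGB frame."""
    arr = validate_frame(frame)
    return arr @ coeffs.as_array()


def mean_luminance(frame: np.ndarray, coeffs: LumaCoefficients = REC601_LUMA) -> float:
    """Scalar mean of the luma plane over all pixels."""
    return float(luminance(frame, coeffs).mean())


def rgb_to_ycbcr(frame: np.ndarray, range_convention: str = "studio") -> YCbCrFrame:
    """Convert an RGB frame to YCbCr planes.

    With the studio convention the Y plane equals the Rec. 601 luma mapped
    affinely onto [16/255, 235/255].
    """
    if range_convention not in _CONVENTIONS:
        raise ValueError(f"unknown range convention {range_convention!r}")
    arr = validate_frame(frame)
    matrix, offset = _CONVENTIONS[range_convention]
    ycc = arr @ matrix.T + offset
    return YCbCrFrame(ycc[..., 0], ycc[..., 1], ycc[..., 2], range_convention)


def ycbcr_to_rgb(ycc: YCbCrFrame) -> np.ndarray:
    """Invert :func:`rgb_to_ycbcr`; output is clipped to the RGB gamut."""
    matrix, offset = _CONVENTIONS[ycc.range_convention]
    inv = np.linalg.inv(matrix)
    planes = np.stack([ycc.y, ycc.cb, ycc.cr], axis=-1) - offset
    return np.clip(planes @ inv.T, 0.0, 1.0)
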