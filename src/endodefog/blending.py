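"""Luminance blending of the enhancement and restoration branches.

Both branch images are moved to YCbCr.  For each branch an illumination
map is estimated by edge-aware recursive filtering of its luma plane, a
smoke-level-dependent weight is derived from that illumination, and every
YCbCr plane is fused as the per-pixel weighted average of the two
branches.  The fused luma is then stretched onto the studio-range window
[P, Q] = [15, 236] (8-bit), recombined with the fused chroma and mapped
back to RGB.

Weight rule: in the heavy-smoke case pixels whose illumination falls in
the 8-bit range [16, 128] receive weight 1; in the thin-smoke case the
interval is [128, 235].  Outside the interval the weight decays linearly
to a small floor over a configurable transition width, which avoids hard
seams between regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .frames import (
    LumaCoefficients,
    REC601_LUMA,
    YCbCrFrame,
    luminance,
    mean_luminance,
    rgb_to_ycbcr,
    validate_frame,
    ycbcr_to_rgb,
)

__all__ = [
    "BlendConfig",
    "estimate_illumination",
    "smoke_weight",
    "classify_smoke",
    "blend_channels",
    "stretch_histogram",
    "recombine",
]

logger = logging.getLogger(__name__)

WEIGHT_FLOOR = 1e-4


@dataclass
class BlendConfig:
    """Blending configuration.

    Intervals and stretch bounds are expressed in 8-bit luma units; they
    are divided by 255 where they meet the unit-interval planes.
    ``smoke_level`` is ``'thin'``, ``'heavy'`` or ``'auto'`` (classify per
    frame).  ``transition_width`` softens the weight-1 interval edges.
    """

    smoke_level: str = "auto"
    heavy_interval: tuple = (16.0, 128.0)
    thin_interval: tuple = (128.0, 235.0)
    stretch_low: float = 15.0
    stretch_high: float = 236.0
    transition_width: float = 16.0

    def __post_init__(self) -> None:
        if self.smoke_level not in ("thin", "heavy", "auto"):
            raise ValueError(f"unknown smoke level {self.smoke_level!r}")
        if not self.stretch_low < self.stretch_high:
            raise ValueError("stretch bounds must satisfy P < Q")
        for lo, hi in (self.heavy_interval, self.thin_interval):
            if not (0 <= lo <= hi <= 255):
                raise ValueError("weight intervals must lie within [0, 255]")
        if self.transition_width < 0:
            raise ValueError("transition width must be non-negative")

    def interval_for(self, level: str) -> tuple:
        if level == "heavy":
            return self.heavy_interval
        if level == "thin":
            return self.thin_interval
        raise ValueError(f"smoke level not resolved: {level!r}")


def _dt_pass_rows(plane: np.ndarray, feedback: np.ndarray) -> np.ndarray:
    """One left-right + right-left recursive pass along rows.

    ``feedback[:, i]`` is the coefficient coupling column i to column i-1.
    """
    out = plane.copy()
    w = plane.shape[1]
    for i in range(1, w):
        out[:, i] += feedback[:, i] * (out[:, i - 1] - out[:, i])
    for i in range(w - 2, -1, -1):
        out[:, i] += feedback[:, i + 1] * (out[:, i + 1] - out[:, i])
    return out


def estimate_illumination(
    image: np.ndarray,
    sigma_spatial: float = 30.0,
    sigma_range: float = 0.2,
    iterations: int = 3,
    coeffs: LumaCoefficients = REC601_LUMA,
) -> np.ndarray:
    """Edge-aware illumination estimate of a frame's luma plane.

    Domain-transform recursive filtering: the luma plane is smoothed by
    causal/anticausal first-order passes along rows then columns whose
    feedback coefficient shrinks across edges of the plane itself.  The
    per-iteration spatial std follows the halving schedule
    ``sigma_i = sigma_spatial * sqrt(3) * 2^(N-i) / sqrt(4^N - 1)`` so the
    cascade's overall variance matches ``sigma_spatial**2``.

    Accepts an RGB frame (luma is taken) or a 2-D luma plane.  A constant
    plane is a fixed point; as ``sigma_range`` approaches zero every edge
    blocks diffusion and the filter tends to the identity.
    """
    if sigma_spatial <= 0 or sigma_range <= 0:
        raise ValueError("sigma_spatial and sigma_range must be positive")
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3:
        plane = luminance(arr, coeffs)
    elif arr.ndim == 2:
        plane = arr.copy()
    else:
        raise ValueError("expected an RGB frame or a 2-D luma plane")

    ratio = sigma_spatial / sigma_range
    # domain-transform derivatives: 1 + (sigma_s/sigma_r) * |dI|
    dx = 1.0 + ratio * np.abs(np.diff(plane, axis=1))
    dy = 1.0 + ratio * np.abs(np.diff(plane, axis=0))
    dx = np.concatenate([np.zeros((plane.shape[0], 1)), dx], axis=1)
    dy = np.concatenate([np.zeros((1, plane.shape[1])), dy], axis=0)

    n = iterations
    out = plane
    for i in range(1, n + 1):
        sigma_i = sigma_spatial * np.sqrt(3.0) * 2.0 ** (n - i) / np.sqrt(4.0**n - 1.0)
        a = np.exp(-np.sqrt(2.0) / sigma_i)
        out = _dt_pass_rows(out, a**dx)
        out = _dt_pass_rows(out.T, (a**dy).T).T
    return np.clip(out, 0.0, 1.0)


def smoke_weight(
    illumination: np.ndarray, cfg: BlendConfig, level: str | None = None
) -> np.ndarray:
    """Blend weight from an illumination map.

    Weight 1 inside the smoke level's 8-bit interval (applied to
    255*illumination), decaying linearly to the floor over
    ``transition_width`` outside it.
    """
    level = level or cfg.smoke_level
    lo, hi = cfg.interval_for(level)
    x = 255.0 * np.asarray(illumination, dtype=np.float64)
    if cfg.transition_width > 0:
        below = 1.0 - (lo - x) / cfg.transition_width
        above = 1.0 - (x - hi) / cfg.transition_width
        w = np.minimum(np.minimum(below, above), 1.0)
    else:
        w = np.where((x >= lo) & (x <= hi), 1.0, 0.0)
    return np.clip(w, WEIGHT_FLOOR, 1.0)


def classify_smoke(frame: np.ndarray, coeffs: LumaCoefficients = REC601_LUMA) -> str:
    """Heavy smoke if mean 8-bit luma < 128, thin otherwise."""
    return "heavy" if 255.0 * mean_luminance(frame, coeffs) < 128.0 else "thin"


def blend_channels(
    restored: np.ndarray,
    enhanced: np.ndarray,
    weight_restored: np.ndarray,
    weight_enhanced: np.ndarray,
    range_convention: str = "studio",
) -> YCbCrFrame:
    """Weighted fusion of the two branches' YCbCr planes.

    O_e = (W_J * J_e + W_L * L_e) / (W_J + W_L) for e in {Y, Cb, Cr};
    every output plane is a pixelwise convex combination of the branch
    planes.
    """
    j = rgb_to_ycbcr(restored, range_convention)
    l = rgb_to_ycbcr(enhanced, range_convention)
    wj = np.asarray(weight_restored, dtype=np.float64)
    wl = np.asarray(weight_enhanced, dtype=np.float64)
    if not (wj.shape == wl.shape == j.y.shape):
        raise ValueError("weight maps and frames must share dimensions")
    total = wj + wl
    planes = [
        (wj * pj + wl * pl) / total
        for pj, pl in ((j.y, l.y), (j.cb, l.cb), (j.cr, l.cr))
    ]
    return YCbCrFrame(*planes, range_convention)


def stretch_histogram(luma_plane: np.ndarray, cfg: BlendConfig | None = None) -> np.ndarray:
    """Affinely stretch a luma plane so its extrema land exactly on
    [P, Q]/255; a constant plane maps to the window midpoint."""
    cfg = cfg or BlendConfig()
    plane = np.asarray(luma_plane, dtype=np.float64)
    p = cfg.stretch_low / 255.0
    q = cfg.stretch_high / 255.0
    lo, hi = plane.min(), plane.max()
    if hi - lo < 1e-12:
        logger.warning("stretch_histogram: constant luma plane, returning midpoint")
        return np.full_like(plane, 0.5 * (p + q))
    return p + (plane - lo) / (hi - lo) * (q - p)


def recombine(
    stretched_y: np.ndarray,
    cb: np.ndarray,
    cr: np.ndarray,
    range_convention: str = "studio",
) -> np.ndarray:
    """Reassemble the stretched luma with the fused chroma into an RGB
    frame, clipped to gamut."""
    return ycbcr_to_rgb(YCbCrFrame(stretched_y, cb, cr, range_convention))
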