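"""Visibility-restoration branch.

Estimates the ambient light and the atmospheric veil, inverts the haze
model, and denoises the result with a joint bilateral filter guided by
the original frame.

The veil X = A*(1-T) sidesteps explicit depth/transmission estimation: it
is bounded above by the darkest colour channel at every pixel (a fog-free
scene point with a dark channel carries no veil) and is recovered with the
median-of-medians construction of the fast visibility-restoration family:

    W = median(M),  B = W - median(|M - W|),  X = clip(min(p*B, M), 0, A)

where M is the pixelwise min-channel map, medians are taken over a square
window, and p in (0, 1] controls restoration strength.  Scene radiance
then follows from F = A*(I - X) / (A - X) per channel.

The joint bilateral filter smooths the restored frame with Gaussian
spatial weights while its range weights come from the *guide* (the
original hazy frame, whose edges are trustworthy):

    J(p) = sum_q F(q) * w(p,q) / sum_q w(p,q)
    w(p,q) = exp(-(|p-q|^2 / 2 sigma_s^2 + (H(p)-H(q))^2 / 2 sigma_c^2))

with H the guide's luma.  Neighbourhoods are truncated at frame borders;
the normaliser keeps the weights summing to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .frames import LumaCoefficients, REC601_LUMA, luminance, validate_frame

__all__ = [
    "VeilParams",
    "BilateralParams",
    "estimate_atmospheric_light",
    "estimate_veil",
    "recover_radiance",
    "joint_bilateral_filter",
]

logger = logging.getLogger(__name__)


@dataclass
class VeilParams:
    """Veil/ambient-light estimation parameters.

    ``window`` is the median-filter half-size in pixels, ``p_factor`` the
    veil strength in (0, 1] (default calibrated for endoscopic scenes, whose
    min-channel floor on pink tissue is far above zero), ``white_balance_a`` fixes the ambient light at
    1.0 (white-balanced frame assumption) instead of estimating it.
    """

    window: int = 7
    p_factor: float = 0.8
    white_balance_a: bool = True

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("median window half-size must be >= 1")
        if not 0.0 < self.p_factor <= 1.0:
            raise ValueError("p_factor must lie in (0, 1]")


@dataclass
class BilateralParams:
    """Joint-bilateral parameters: spatial std (px), range std (intensity),
    window half-size (defaults to round(3*sigma_s))."""

    sigma_s: float = 3.0
    sigma_c: float = 0.1
    radius: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_s <= 0 or self.sigma_c <= 0:
            raise ValueError("sigma_s and sigma_c must be positive")
        if self.radius is None:
            self.radius = max(1, int(round(3 * self.sigma_s)))
        if self.radius < 1:
            raise ValueError("radius must be >= 1")


def estimate_atmospheric_light(
    frame: np.ndarray, params: VeilParams | None = None
) -> float:
    """Ambient light A: 1.0 under the white-balance convention, otherwise
    the mean luminance over the 0.1% of pixels with the brightest
    min-channel (dark-channel) values — the most fog-opaque pixels, where
    the observed intensity converges to A."""
    params = params or VeilParams()
    if params.white_balance_a:
        return 1.0
    arr = validate_frame(frame)
    dark = arr.min(axis=2).ravel()
    n_top = max(1, int(round(0.001 * dark.size)))
    idx = np.argpartition(dark, -n_top)[-n_top:]
    luma = luminance(arr).ravel()
    return float(luma[idx].mean())


def estimate_veil(
    frame: np.ndarray, atmospheric_light: float, params: VeilParams | None = None
) -> np.ndarray:
    """Median-of-medians atmospheric-veil estimate, clipped so that
    0 <= X <= min-channel and X <= A pixelwise."""
    params = params or VeilParams()
    arr = validate_frame(frame)
    size = 2 * params.window + 1
    if size > min(arr.shape[0], arr.shape[1]):
        raise ValueError(
            f"median window {size} exceeds frame size {arr.shape[:2]}"
        )
    min_channel = arr.min(axis=2)
    local = ndimage.median_filter(min_channel, size=size, mode="nearest")
    deviation = ndimage.median_filter(
        np.abs(min_channel - local), size=size, mode="nearest"
    )
    veil = params.p_factor * (local - deviation)
    return np.clip(np.minimum(veil, min_channel), 0.0, atmospheric_light)


def recover_radiance(
    frame: np.ndarray,
    veil: np.ndarray,
    atmospheric_light: float,
    eps: float = 1e-3,
) -> np.ndarray:
    """Invert the haze model: F = A*(I - X) / (A - X), clipped to [0, 1].

    Where the denominator A - X would fall below ``eps`` (veil saturating
    the ambient light) it is clamped rather than raising, and the event is
    logged.
    """
    arr = validate_frame(frame)
    x = np.asarray(veil, dtype=np.float64)
    if x.shape != arr.shape[:2]:
        raise ValueError(f"veil shape {x.shape} does not match frame {arr.shape[:2]}")
    denom = atmospheric_light - x
    n_clamped = int((denom < eps).sum())
    if n_clamped:
        logger.debug(
            "recover_radiance: clamped denominator at %d pixels (A - X < %g)",
            n_clamped,
            eps,
        )
    denom = np.maximum(denom, eps)
    radiance = atmospheric_light * (arr - x[..., None]) / denom[..., None]
    return np.clip(radiance, 0.0, 1.0)


def joint_bilateral_filter(
    restored: np.ndarray,
    guide: np.ndarray,
    params: BilateralParams | None = None,
    coeffs: LumaCoefficients = REC601_LUMA,
) -> np.ndarray:
    """Edge-preserving smoothing of ``restored`` with range weights from
    the guide's luma.

    The output at each pixel is a convex combination of neighbourhood
    values, so it always lies within the neighbourhood's [min, max].
    """
    params = params or BilateralParams()
    src = validate_frame(restored, "restored")
    gde = validate_frame(guide, "guide")
    if src.shape != gde.shape:
        raise ValueError("restored and guide frames must share dimensions")
    guide_luma = gde @ coeffs.as_array()
    r = params.radius
    h, w = src.shape[:2]
    accum = np.zeros_like(src)
    weight_sum = np.zeros((h, w))
    inv_2ss = 1.0 / (2.0 * params.sigma_s**2)
    inv_2sc = 1.0 / (2.0 * params.sigma_c**2)
    for dy in range(-r, r + 1):
        ys_dst = slice(max(0, dy), h + min(0, dy))
        ys_src = slice(max(0, -dy), h + min(0, -dy))
        for dx in range(-r, r + 1):
            xs_dst = slice(max(0, dx), w + min(0, dx))
            xs_src = slice(max(0, -dx), w + min(0, -dx))
            spatial = np.exp(-(dy * dy + dx * dx) * inv_2ss)
            diff = guide_luma[ys_dst, xs_dst] - guide_luma[ys_src, xs_src]
            wgt = spatial * np.exp(-(diff * diff) * inv_2sc)
            accum[ys_dst, xs_dst] += wgt[..., None] * src[ys_src, xs_src]
            weight_sum[ys_dst, xs_dst] += wgt
    return accum / weight_sum[..., None]
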