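"""Forward haze model and synthetic foggy-frame generator.

Koschmieder's law describes the observed intensity of a scene seen through
a scattering medium as a per-pixel convex mix of the haze-free radiance F
and the ambient (atmospheric) light A:

    I = F * T + A * (1 - T),        T = exp(-k * d)

where the transmission T is the fraction of unscattered light reaching the
camera, k the scattering coefficient and d the scene depth.  The additive
term X = A * (1 - T) is the *atmospheric veil*.

The generator in this module composites clean endoscopy-like frames
(tissue gradients, vessel curves, checkerboards) with known transmission
fields so that every downstream stage can be tested against ground truth.
Surgical smoke is emulated either as a homogeneous layer or as a smooth
low-frequency random "plume" field; the *thin* preset keeps transmission
in [0.6, 0.9] and the *heavy* preset in [0.15, 0.5], with the ambient
light near white (0.95), emulating the wispy and dense smoke regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .frames import from_uint8, to_uint8, validate_frame

__all__ = [
    "FogSimParams",
    "ScenePreset",
    "THIN_SMOKE",
    "HEAVY_SMOKE",
    "transmission_from_depth",
    "apply_fog",
    "veil_from_transmission",
    "generate_scene",
    "simulate_foggy_frame",
]


@dataclass
class FogSimParams:
    """Physical parameters of the forward haze model.

    k is the scattering factor per unit depth, ``depth`` the camera-to-scene
    distance map (arbitrary length units), ``atmospheric_light`` the ambient
    level the veil converges to, ``noise_sigma`` the std of additive
    Gaussian sensor noise.
    """

    k: float = 1.0
    depth: np.ndarray | None = None
    atmospheric_light: float = 0.95
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("scattering factor k must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not 0.0 < self.atmospheric_light <= 1.0:
            raise ValueError("atmospheric light must lie in (0, 1]")
        if self.depth is not None and np.asarray(self.depth).min() < 0:
            raise ValueError("depth must be non-negative everywhere")


@dataclass(frozen=True)
class ScenePreset:
    """Smoke-level fixture preset: transmission range and ambient light."""

    name: str
    t_min: float
    t_max: float
    atmospheric_light: float = 0.95


THIN_SMOKE = ScenePreset("thin", 0.6, 0.9)
HEAVY_SMOKE = ScenePreset("heavy", 0.15, 0.5)

_PRESETS = {"thin": THIN_SMOKE, "heavy": HEAVY_SMOKE}


def transmission_from_depth(k: float, depth: np.ndarray) -> np.ndarray:
    """Transmission map T = exp(-k * d); values fall in (0, 1]."""
    depth = np.asarray(depth, dtype=np.float64)
    if k < 0:
        raise ValueError("scattering factor k must be non-negative")
    if depth.min() < 0:
        raise ValueError("depth must be non-negative everywhere")
    return np.exp(-k * depth)


def apply_fog(
    clean: np.ndarray,
    transmission: np.ndarray,
    atmospheric_light: float = 0.95,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    quantize: bool = False,
) -> np.ndarray:
    """Composite a clean frame with fog: I = F*T + A*(1-T) (+ noise).

    With ``quantize`` the result is rounded through 8 bits, mimicking real
    acquisition before the frame enters the defogging pipeline.
    """
    clean = validate_frame(clean, "clean")
    t = np.asarray(transmission, dtype=np.float64)
    if t.shape != clean.shape[:2]:
        raise ValueError(
            f"transmission shape {t.shape} does not match frame {clean.shape[:2]}"
        )
    hazy = clean * t[..., None] + atmospheric_light * (1.0 - t[..., None])
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        hazy = hazy + rng.normal(0.0, noise_sigma, size=hazy.shape)
    hazy = np.clip(hazy, 0.0, 1.0)
    if quantize:
        hazy = from_uint8(to_uint8(hazy))
    return hazy


def veil_from_transmission(
    transmission: np.ndarray, atmospheric_light: float
) -> np.ndarray:
    """Atmospheric veil X = A * (1 - T), the additive haze layer."""
    t = np.asarray(transmission, dtype=np.float64)
    return atmospheric_light * (1.0 - t)


def _gradient_scene(height: int, width: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth tissue-coloured illumination gradient with the dynamic range
    of real endoscopy: bright on-axis lighting, specular highlights off the
    wet mucosa, and a dark lumen/shadow region."""
    yy, xx = np.meshgrid(
        np.linspace(0, 1, height), np.linspace(0, 1, width), indexing="ij"
    )
    cx, cy = rng.uniform(0.3, 0.7, size=2)
    radial = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    # endoscopes carry their own light source: tissue is brightly lit near
    # the optical axis and falls off toward the periphery
    shade = 1.05 - 0.55 * radial + 0.06 * np.sin(8 * np.pi * xx + rng.uniform(0, 2 * np.pi))
    shade = np.clip(shade, 0.15, 1.0)
    base = np.array([0.88, 0.52, 0.42])  # brightly lit mucosal pink
    frame = shade[..., None] * base

    # dark lumen / cavity: deep shadow blob away from the light centre
    lx, ly = rng.uniform(0.1, 0.9, size=2)
    lumen = np.exp(
        -(((xx - lx) ** 2 + (yy - ly) ** 2)) / (2 * rng.uniform(0.06, 0.12) ** 2)
    )
    frame = frame * (1.0 - 0.95 * lumen[..., None])

    # specular highlights: small saturated spots near the light centre
    for _ in range(rng.integers(3, 7)):
        sx = np.clip(cx + rng.normal(0, 0.15), 0.05, 0.95)
        sy = np.clip(cy + rng.normal(0, 0.15), 0.05, 0.95)
        spot = np.exp(
            -(((xx - sx) ** 2 + (yy - sy) ** 2)) / (2 * rng.uniform(0.004, 0.012) ** 2)
        )
        frame = frame + (1.0 - frame) * spot[..., None]
    return np.clip(frame, 0.0, 1.0)


def _vessel_scene(height: int, width: int, rng: np.random.Generator) -> np.ndarray:
    """Tissue background overlaid with dark curved vessel strokes."""
    frame = _gradient_scene(height, width, rng)
    mask = np.zeros((height, width))
    n_vessels = 12
    t = np.linspace(0, 1, 4 * max(height, width))
    for _ in range(n_vessels):
        # quadratic Bezier with random control points spanning the frame
        p = rng.uniform([-0.2, -0.2], [1.2, 1.2], size=(3, 2))
        curve = (
            (1 - t)[:, None] ** 2 * p[0]
            + 2 * (1 - t)[:, None] * t[:, None] * p[1]
            + t[:, None] ** 2 * p[2]
        )
        rows = np.rint(curve[:, 1] * (height - 1)).astype(int)
        cols = np.rint(curve[:, 0] * (width - 1)).astype(int)
        ok = (rows >= 0) & (rows < height) & (cols >= 0) & (cols < width)
        mask[rows[ok], cols[ok]] = 1.0
    mask = np.clip(ndimage.grey_dilation(mask, size=(2, 2)), 0, 1)
    mask = ndimage.gaussian_filter(mask, 0.6)
    vessel_colour = np.array([0.35, 0.08, 0.08])
    return np.clip(
        frame * (1 - mask[..., None]) + vessel_colour * mask[..., None], 0.0, 1.0
    )


def _checker_scene(height: int, width: int, rng: np.random.Generator) -> np.ndarray:
    block = max(4, min(height, width) // 12)
    yy, xx = np.meshgrid(np.arange(height), np.arange(width), indexing="ij")
    checker = ((yy // block + xx // block) % 2).astype(np.float64)
    c0 = np.array([0.25, 0.25, 0.25])
    c1 = np.array([0.85, 0.85, 0.85])
    return checker[..., None] * c1 + (1 - checker[..., None]) * c0


_SCENES = {"gradient": _gradient_scene, "vessels": _vessel_scene, "checker": _checker_scene}


def _plume_field(
    height: int,
    width: int,
    t_min: float,
    t_max: float,
    smoothness: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smooth low-frequency transmission field rescaled onto [t_min, t_max]."""
    noise = rng.standard_normal((height, width))
    smooth = ndimage.gaussian_filter(noise, sigma=smoothness, mode="nearest")
    lo, hi = smooth.min(), smooth.max()
    if hi - lo < 1e-12:
        return np.full((height, width), 0.5 * (t_min + t_max))
    return t_min + (smooth - lo) / (hi - lo) * (t_max - t_min)


def generate_scene(
    width: int,
    height: int,
    scene_kind: str = "vessels",
    smoke_kind: str = "plume",
    seed: int = 0,
    t_min: float = 0.15,
    t_max: float = 0.5,
    smoothness: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate a clean frame and a ground-truth transmission field.

    Returns ``(clean, transmission)``.  ``smoke_kind='homogeneous'`` draws a
    single constant transmission uniformly from [t_min, t_max]; ``'plume'``
    produces a Gaussian-smoothed random field spanning exactly that range,
    reproducing the inhomogeneous-smoke case.  Reproducible given ``seed``.
    """
    if width < 16 or height < 16:
        raise ValueError("scene dimensions must be at least 16x16")
    if scene_kind not in _SCENES:
        raise ValueError(f"unknown scene kind {scene_kind!r}")
    if smoke_kind not in ("homogeneous", "plume"):
        raise ValueError(f"unknown smoke kind {smoke_kind!r}")
    if not 0.0 <= t_min <= t_max <= 1.0:
        raise ValueError("require 0 <= t_min <= t_max <= 1")
    rng = np.random.default_rng(seed)
    clean = _SCENES[scene_kind](height, width, rng)
    if smoke_kind == "homogeneous":
        value = t_min if t_min == t_max else rng.uniform(t_min, t_max)
        transmission = np.full((height, width), value)
    else:
        if smoothness is None:
            smoothness = min(height, width) / 6.0
        transmission = _plume_field(height, width, t_min, t_max, smoothness, rng)
    return clean, transmission


def simulate_foggy_frame(
    width: int,
    height: int,
    preset: str | ScenePreset = "heavy",
    scene_kind: str = "vessels",
    smoke_kind: str = "plume",
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> dict:
    """One-call fixture: clean frame, transmission, veil and quantized hazy frame.

    Returns a dict with keys ``clean``, ``transmission``, ``veil``, ``hazy``,
    ``atmospheric_light`` and ``preset``.
    """
    if isinstance(preset, str):
        try:
            preset = _PRESETS[preset]
        except KeyError:
            raise ValueError(f"unknown preset {preset!r}") from None
    clean, transmission = generate_scene(
        width,
        height,
        scene_kind=scene_kind,
        smoke_kind=smoke_kind,
        seed=seed,
        t_min=preset.t_min,
        t_max=preset.t_max,
    )
    hazy = apply_fog(
        clean,
        transmission,
        preset.atmospheric_light,
        noise_sigma=noise_sigma,
        seed=seed + 1,
        quantize=True,
    )
    return {
        "clean": clean,
        "transmission": transmission,
        "veil": veil_from_transmission(transmission, preset.atmospheric_light),
        "hazy": hazy,
        "atmospheric_light": preset.atmospheric_light,
        "preset": preset.name,
    }
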