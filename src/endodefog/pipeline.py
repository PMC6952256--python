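"""End-to-end defogging pipeline and its configuration.

Per frame the pipeline runs the two branches independently and fuses
them:

1. enhancement: L = clip(0.5 + beta*(I - lambda))
2. restoration: estimate ambient light and veil, invert the haze model,
   joint-bilateral-filter the result guided by the original frame
3. blending: per-branch illumination maps, smoke-level weights, weighted
   YCbCr fusion, luma stretch onto [P, Q], recombination to RGB

The pipeline itself is deterministic: the same frame and configuration
always produce bitwise-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import blending, enhancement, metrics, restoration
from .blending import BlendConfig
from .frames import validate_frame
from .metrics import NaturalnessParams, QualityReport, evaluate_sequence
from .restoration import BilateralParams, VeilParams

__all__ = ["IlluminationConfig", "PipelineConfig", "defog_frame", "defog_sequence"]

logger = logging.getLogger(__name__)


@dataclass
class IlluminationConfig:
    """Recursive-filter parameters for illumination estimation."""

    sigma_spatial: float = 30.0
    sigma_range: float = 0.2
    iterations: int = 3


@dataclass
class PipelineConfig:
    """Full pipeline configuration, serialisable to YAML/JSON.

    The defaults reproduce the method's stated constants: Rec. 601 luma
    weights, stretch bounds P = 15 / Q = 236, weight intervals [16, 128]
    (heavy) and [128, 235] (thin), hybrid-metric gamma = 0.6.
    """

    beta: float = 4.0 / 3.0
    recenter: bool = True
    veil: VeilParams = field(default_factory=VeilParams)
    bilateral: BilateralParams = field(default_factory=BilateralParams)
    illumination: IlluminationConfig = field(default_factory=IlluminationConfig)
    blend: BlendConfig = field(default_factory=BlendConfig)
    gamma: float = metrics.DEFAULT_GAMMA
    range_convention: str = "studio"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "veil" in data and isinstance(data["veil"], dict):
            data["veil"] = VeilParams(**data["veil"])
        if "bilateral" in data and isinstance(data["bilateral"], dict):
            data["bilateral"] = BilateralParams(**data["bilateral"])
        if "illumination" in data and isinstance(data["illumination"], dict):
            data["illumination"] = IlluminationConfig(**data["illumination"])
        if "blend" in data and isinstance(data["blend"], dict):
            blend = dict(data["blend"])
            for key in ("heavy_interval", "thin_interval"):
                if key in blend:
                    blend[key] = tuple(blend[key])
            data["blend"] = BlendConfig(**blend)
        return cls(**data)


def defog_frame(
    frame: np.ndarray,
    cfg: PipelineConfig | None = None,
    smoke_level: str | None = None,
    return_intermediates: bool = False,
):
    """Defog one frame; returns the defogged frame (and, on request, a
    dict of intermediate stage outputs).

    ``smoke_level`` overrides the configured level (used by the sequence
    driver's majority vote); ``'auto'`` classifies the frame itself.
    """
    cfg = cfg or PipelineConfig()
    frame = validate_frame(frame)
    level = smoke_level or cfg.blend.smoke_level
    if level == "auto":
        level = blending.classify_smoke(frame)
    logger.debug("defog_frame: smoke level %s", level)

    enhanced = enhancement.enhance_contrast(
        frame, beta=cfg.beta, recenter=cfg.recenter
    ).image

    ambient = restoration.estimate_atmospheric_light(frame, cfg.veil)
    veil = restoration.estimate_veil(frame, ambient, cfg.veil)
    radiance = restoration.recover_radiance(frame, veil, ambient)
    restored = restoration.joint_bilateral_filter(radiance, frame, cfg.bilateral)

    illum = cfg.illumination
    g_restored = blending.estimate_illumination(
        restored, illum.sigma_spatial, illum.sigma_range, illum.iterations
    )
    g_enhanced = blending.estimate_illumination(
        enhanced, illum.sigma_spatial, illum.sigma_range, illum.iterations
    )
    w_restored = blending.smoke_weight(g_restored, cfg.blend, level)
    w_enhanced = blending.smoke_weight(g_enhanced, cfg.blend, level)

    fused = blending.blend_channels(
        restored, enhanced, w_restored, w_enhanced, cfg.range_convention
    )
    stretched = blending.stretch_histogram(fused.y, cfg.blend)
    out = blending.recombine(stretched, fused.cb, fused.cr, cfg.range_convention)

    if return_intermediates:
        return out, {
            "smoke_level": level,
            "enhanced": enhanced,
            "ambient_light": ambient,
            "veil": veil,
            "radiance": radiance,
            "restored": restored,
            "illumination_restored": g_restored,
            "illumination_enhanced": g_enhanced,
            "weight_restored": w_restored,
            "weight_enhanced": w_enhanced,
            "fused_luma": fused.y,
        }
    return out


def defog_sequence(
    frames: list,
    cfg: PipelineConfig | None = None,
    majority_vote: bool = False,
) -> tuple:
    """Defog a frame sequence; returns (defogged frames, QualityReport).

    With ``majority_vote`` and ``smoke_level='auto'`` the per-frame
    classification is replaced by the sequence majority (ties break to
    thin), avoiding smoke-level flicker between consecutive frames.
    """
    if not frames:
        raise ValueError("empty frame sequence")
    cfg = cfg or PipelineConfig()
    level = None
    if majority_vote and cfg.blend.smoke_level == "auto":
        votes = [blending.classify_smoke(f) for f in frames]
        n_heavy = sum(v == "heavy" for v in votes)
        level = "heavy" if n_heavy > len(frames) / 2 else "thin"
        logger.info(
            "defog_sequence: majority vote %s (%d/%d heavy)",
            level,
            n_heavy,
            len(frames),
        )
    outputs = []
    for i, frame in enumerate(frames):
        outputs.append(defog_frame(frame, cfg, smoke_level=level))
        logger.debug("defog_sequence: frame %d/%d done", i + 1, len(frames))
    report = evaluate_sequence(outputs, frames, gamma=cfg.gamma)
    logger.info(
        "defog_sequence: %d frames, mean psi %.4f",
        len(outputs),
        report.aggregates["psi"],
    )
    return outputs, report
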