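"""Image-quality assessment: SSIM, statistical naturalness and the hybrid
score psi.

The hybrid score combines a reference-based structural term with a
no-reference naturalness term,

    psi = gamma * S + (1 - gamma) * N,      gamma = 0.6 by default,

where S is the mean single-scale SSIM between the luma planes of the test
and reference frames (11x11 Gaussian window, sigma = 1.5, stabilisers
K1 = 0.01, K2 = 0.03, dynamic range 1) and N rates global brightness and
contrast against priors fitted to large natural-image corpora: a Gaussian
density on the mean 8-bit luma (mu = 115.94, sigma = 27.99) times a
Beta(4.4, 10.1) density on the contrast — the mean over the frame of the
local (11x11 window) luma standard deviation, scaled by 64.29 — each
normalised by its maximum so an ideally exposed image scores 1.

For clinical footage no haze-free ground truth exists, so the reference
for S is the original foggy frame; when a simulation provides clean
truth, :func:`evaluate_sequence` reports SSIM against truth in separate
columns as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.metrics import structural_similarity

from .frames import luminance, validate_frame

__all__ = [
    "NaturalnessParams",
    "QualityReport",
    "ssim",
    "naturalness",
    "hybrid_quality",
    "evaluate_sequence",
]

DEFAULT_GAMMA = 0.6


@dataclass(frozen=True)
class NaturalnessParams:
    """Priors of the statistical-naturalness score (8-bit luma scale)."""

    mean_mu: float = 115.94
    mean_sigma: float = 27.99
    contrast_alpha: float = 4.4
    contrast_beta: float = 10.1
    contrast_scale: float = 64.29
    contrast_window: int = 11

    @property
    def contrast_mode(self) -> float:
        a, b = self.contrast_alpha, self.contrast_beta
        return (a - 1.0) / (a + b - 2.0)


def ssim(test: np.ndarray, reference: np.ndarray) -> float:
    """Mean single-scale SSIM between the luma planes of two frames."""
    t = validate_frame(test, "test")
    r = validate_frame(reference, "reference")
    if t.shape != r.shape:
        raise ValueError("test and reference frames must share dimensions")
    return float(
        structural_similarity(
            luminance(t),
            luminance(r),
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
            data_range=1.0,
        )
    )


def naturalness(
    frame: np.ndarray, params: NaturalnessParams = NaturalnessParams()
) -> float:
    """Statistical naturalness in [0, 1].

    Product of a Gaussian brightness prior evaluated at the frame's mean
    8-bit luma and a Beta contrast prior evaluated at the mean local
    (``contrast_window``-sized) luma std over ``contrast_scale``,
    normalised so the joint maximum is 1.
    """
    from scipy.ndimage import uniform_filter

    luma = luminance(frame)
    mean_8bit = 255.0 * float(luma.mean())
    win = min(params.contrast_window, *luma.shape)
    local_mean = uniform_filter(luma, size=win, mode="reflect")
    local_sq = uniform_filter(luma * luma, size=win, mode="reflect")
    local_var = np.maximum(local_sq - local_mean * local_mean, 0.0)
    std_8bit = 255.0 * float(np.sqrt(local_var).mean())
    p_mean = np.exp(-0.5 * ((mean_8bit - params.mean_mu) / params.mean_sigma) ** 2)
    x = min(std_8bit / params.contrast_scale, 1.0)
    dist = stats.beta(params.contrast_alpha, params.contrast_beta)
    p_contrast = dist.pdf(x) / dist.pdf(params.contrast_mode)
    return float(p_mean * p_contrast)


def hybrid_quality(s: float, n: float, gamma: float = DEFAULT_GAMMA) -> float:
    """Hybrid score psi = gamma * S + (1 - gamma) * N."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    return gamma * s + (1.0 - gamma) * n


@dataclass
class QualityReport:
    """Per-frame quality rows plus arithmetic-mean aggregates."""

    per_frame: pd.DataFrame
    gamma: float = DEFAULT_GAMMA

    @property
    def aggregates(self) -> dict:
        numeric = self.per_frame.select_dtypes("number")
        return {col: float(numeric[col].mean()) for col in numeric.columns}

    def to_csv(self, path) -> None:
        self.per_frame.to_csv(path, index=False)

    def to_json(self) -> dict:
        return {"gamma": self.gamma, "aggregates": self.aggregates,
                "n_frames": int(len(self.per_frame))}


def evaluate_sequence(
    defogged: list,
    originals: list,
    gamma: float = DEFAULT_GAMMA,
    truths: list | None = None,
    params: NaturalnessParams = NaturalnessParams(),
) -> QualityReport:
    """Score a defogged sequence against the original foggy frames.

    Per frame: S = SSIM(defogged, original), N = naturalness(defogged),
    psi = gamma*S + (1-gamma)*N.  With ``truths`` given, SSIM against the
    clean ground truth is reported in an extra column.
    """
    if len(defogged) != len(originals):
        raise ValueError("defogged and original sequences must have equal length")
    if truths is not None and len(truths) != len(defogged):
        raise ValueError("truth sequence length mismatch")
    rows = []
    for i, (out, src) in enumerate(zip(defogged, originals)):
        s = ssim(out, src)
        n = naturalness(out, params)
        row = {
            "frame_id": i,
            "ssim": s,
            "naturalness": n,
            "psi": hybrid_quality(s, n, gamma),
        }
        if truths is not None:
            row["ssim_vs_truth"] = ssim(out, truths[i])
        rows.append(row)
    return QualityReport(pd.DataFrame(rows), gamma=gamma)
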