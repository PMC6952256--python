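# Methods

This note records the model, the parameter choices, the synthetic-data
design and the numerical conventions behind `endodefog`, including the
places where the underlying method is under-specified and a concrete
design decision had to be made.

## Imaging model and pipeline

All processing happens in floating point on the unit interval; 8-bit
frames are divided by 255 at the I/O boundary and re-quantized only on
write. Every 8-bit constant in the pipeline (studio luma bounds 16/235,
weight intervals, stretch bounds 15/236) is divided by 255 at the module
boundary, so the multi-stage pipeline is never quantized internally.

Haze formation follows Koschmieder's law `I = F·T + A∞(1−T)` with
transmission `T = exp(−k·d)`. The defogger never estimates `T` directly;
it works with the atmospheric veil `X = A∞(1−T)`, whose estimate needs no
depth information.

Pipeline per frame (deterministic; no randomness anywhere in the path):

1. enhancement branch `L_c = clip(0.5 + β(I_c − λ))`;
2. restoration branch: veil estimate → model inversion → joint bilateral;
3. YCbCr fusion with illumination weights, luma stretch, recombination.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| β (enhancement gain) | 4/3 | — | inverse of the thin-smoke preset's mean transmission (≈0.75): the gain that undoes a thin veil's contrast compression without clipping the re-centred branch. |
| veil median window half-size | 7 | px | the fast-visibility convention of a window comparable to the largest expected smoke-free object detail. |
| veil strength p | 0.8 | — | calibrated on the simulator for restoration fidelity (mean abs error of recovered radiance vs truth): thin smoke favours ≈0.6, heavy ≈0.85; 0.8 balances both. The road-scene convention of 0.95 assumes scenes containing near-black objects; pink mucosa's min channel is far above zero, and 0.95 visibly over-darkens the restored branch. |
| A∞ convention | fixed 1.0 | — | white-balanced-frame assumption; an estimator mode (mean luminance over the top 0.1 % brightest dark-channel pixels) is provided for unbalanced input and recovers a true A∞ = 0.95 within 0.05 on the heavy preset. |
| bilateral σ_s / σ_c / radius | 3 px / 0.1 / 3σ_s | px, intensity | standard edge-preserving denoise scale for video-resolution frames; σ_c of 0.1 keeps range weights selective at typical tissue-edge contrasts. |
| illumination σ_spatial / σ_range / iterations | 30 px / 0.2 / 3 | px, intensity | canonical domain-transform recursive-filter defaults; 3 iterations with the halving σ schedule approximate a large Gaussian while respecting edges. |
| weight intervals | [16,128] heavy, [128,235] thin | 8-bit luma | the method's stated weight-1 intervals; applied to each branch's own illumination map. |
| transition width | 16 | 8-bit luma | linear ramp softening the interval edges, avoiding visible seams; weights are floored at 1e-4 so the fused denominator never vanishes. |
| stretch bounds P, Q | 15, 236 | 8-bit luma | the method's stated histogram-stretch window. |
| metric γ | 0.6 | — | the stated SSIM/naturalness balance. |
| naturalness priors | μ=115.94, σ=27.99; Beta(4.4, 10.1), scale 64.29 | 8-bit luma | the statistical-naturalness priors fitted to large natural-image corpora; contrast is the mean local (11×11) luma std, which is what those priors were fitted to — a global std misreads any sharp image as unnatural. All five values are configurable. |

Interpretation decisions where the method is ambiguous:

- The bilateral kernel is implemented with a negated exponent (the only
  decaying choice); the blending equation is read as the weighted average
  of the two branches' YCbCr planes; weights come from each branch's own
  illumination map.
- The enhancement output is re-centred at 0.5 before clipping so the
  branch is a displayable, in-gamut image prior to fusion.
- YCbCr uses BT.601 studio-range matrices, making the 8-bit constants
  above directly meaningful on the luma plane; a full-range variant is
  available.
- `auto` smoke level classifies a frame as heavy when its mean 8-bit luma
  is below 128 (ties go to thin); sequences can resolve the level once by
  majority vote to avoid flicker.

## Synthetic-fog simulator

The simulator provides the ground truth that clinical footage cannot:
clean frames are endoscopy-like scenes (brightly lit mucosal-pink
gradients, dark vessel curves, specular highlights, a dark lumen region —
giving frames the near-full dynamic range real endoscopy has; the global
luma stretch presumes that range), fogged by either a homogeneous layer or
a Gaussian-smoothed random "plume" field emulating inhomogeneous smoke.
Presets: *thin* `T ∈ [0.6, 0.9]`, *heavy* `T ∈ [0.15, 0.5]`, both with
ambient light 0.95. Hazy outputs are clipped and quantized through 8 bits
before entering the pipeline, mimicking acquisition. Sensor noise is off
by default and available as an option.

What the simulator does **not** emulate: fluid-dynamic smoke motion and
temporal correlation, specular bloom and lens flare, chromatic ambient
light, debayering/compression artifacts, and the statistical texture of
real tissue. Passing the synthetic tests therefore demonstrates the
algebraic and structural correctness of the pipeline and its behaviour
across smoke densities, not clinical image quality.

## Numerical choices

- Model inversion clamps the denominator `A∞ − X` at 1e-3 (logged) rather
  than raising; output is clipped to gamut.
- Bilateral and median neighbourhoods truncate at frame borders; the
  bilateral normaliser re-normalizes truncated windows.
- The histogram stretch maps the plane's observed extrema affinely onto
  [15, 236]/255; a constant plane returns the window midpoint with a
  logged warning.
- The weight ramp is exactly linear over the transition width and floored
  at 1e-4; with transition width 0 the intervals are hard.
- SSIM is single-scale with an 11×11 Gaussian window (σ = 1.5), K1 = 0.01,
  K2 = 0.03, dynamic range 1, computed on luma.

## Problem sizes

End-to-end validation runs 20 thin and 20 heavy seeded scenes at 480×270
(one frame per scene), the module tests use 96×72 to 240×160 fixtures, and
the inversion check runs 100 random fixtures at up to 48×48.

## Known limitations

- **Thin-smoke improvement has a failure mode.** On plume realizations
  whose mean transmission exceeds ≈0.8 the hazy frame is already ≥0.96
  SSIM-similar to the clean truth. The pipeline is not an identity map —
  it magnifies contrast, fuses with an aggressively restored branch and
  re-stretches the luma — so its output plateaus near 0.95 similarity for
  any input, and the "defogged closer to truth than hazy" property fails
  on that mild tail (it holds on all heavy-preset frames and on thin
  frames with substantive fog; naturalness improves on all presets). This
  is a property of the method, not of a particular parameter setting.
- The veil estimator inherits the min-channel assumption; on scenes whose
  darkest channel is nowhere near zero it over-estimates the veil, which
  is why the strength default is calibrated down from the road-scene
  convention.
- Colour fidelity is limited: fusing chroma planes from a strongly
  restored branch can desaturate or tint regions where both weights are
  floored.
- Frame-sequence I/O only; video containers must be unpacked to numbered
  frames externally.
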