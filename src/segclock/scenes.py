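"""Synthetic brightfield/fluorescence scenes with ground-truth masks.

One cell per field of view, as in the culture imaging: a textured blob with
a dark rim drifting slightly about the image centre over a speckled
background.  Fluorescence stacks carry the rendered Her1/Mesp trace value
inside the ground-truth mask, so masked means recover the trace directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .presets import GeneratorPreset
from .synth import CellProgram, _her1_values, _mesp_values

__all__ = ["AppearanceParams", "SyntheticScene", "generate_brightfield_scene"]


@dataclass(frozen=True)
class AppearanceParams:
    """Rendering parameters of the synthetic brightfield cell."""

    image_size: int = 96
    radius: float = 20.0  # px
    rim_width: float = 1.5  # px
    rim_inset: float = 1.5  # px: dark rim sits just inside the boundary
    rim_depth: float = 0.55  # brightfield rim darkening
    interior_texture: float = 0.08
    background_level: float = 0.6
    background_speckle: float = 0.03
    drift_step: float = 0.4  # px / frame random walk
    fluor_noise_sd: float = 0.0  # per-pixel fluorescence noise

    def __post_init__(self):
        if self.image_size < 64:
            raise ValueError("image size must be at least 64 x 64")
        if self.radius > 0.35 * self.image_size:
            raise ValueError("blob radius too large for the frame")


@dataclass(frozen=True)
class SyntheticScene:
    frames: np.ndarray  # T x H x W brightfield
    masks: np.ndarray  # T x H x W bool ground truth
    her1_stack: np.ndarray
    mesp_stack: np.ndarray
    program: CellProgram
    times: np.ndarray
    frame_interval: float


def generate_brightfield_scene(program: CellProgram, preset: GeneratorPreset,
                               appearance: AppearanceParams | None = None,
                               seed: int = 0,
                               n_frames: int | None = None) -> SyntheticScene:
    """Render one cell's brightfield + fluorescence stacks with ground-truth
    masks.  Deterministic given the seed; the blob's centre performs a
    reflected random walk confined to < 10% of the image width from centre."""
    ap = appearance or AppearanceParams()
    rng = np.random.default_rng([seed])
    size = ap.image_size
    if n_frames is None:
        n_frames = int(np.floor(
            (preset.duration - preset.imaging_start_offset) / preset.frame_interval
        )) + 1
    times = preset.imaging_start_offset + preset.frame_interval * np.arange(n_frames)
    her1_sig = _her1_values(times, program, preset)
    mesp_sig = _mesp_values(times, program, preset)

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    centre = np.array([size / 2.0, size / 2.0])
    max_drift = 0.095 * size
    # fixed per-cell interior texture, carried with the blob
    tex_grid = rng.normal(0.0, ap.interior_texture, size=(size, size))

    frames = np.empty((n_frames, size, size))
    masks = np.empty((n_frames, size, size), dtype=bool)
    her1 = np.empty_like(frames)
    mesp = np.empty_like(frames)
    pos = centre.copy()
    for t in range(n_frames):
        step = rng.normal(0.0, ap.drift_step, size=2)
        pos = pos + step
        # reflect back inside the allowed drift radius
        off = pos - centre
        r = np.hypot(*off)
        if r > max_drift:
            pos = centre + off * (max_drift / r)
        d = np.hypot(yy - pos[0], xx - pos[1])
        mask = d <= ap.radius
        rim = np.exp(-0.5 * ((d - (ap.radius - ap.rim_inset)) / ap.rim_width) ** 2)
        rim[d > ap.radius] = 0.0  # membrane-like rim confined to the cell
        bf = np.full((size, size), ap.background_level)
        if ap.background_speckle > 0:
            bf += rng.normal(0.0, ap.background_speckle, size=(size, size))
        bf -= ap.rim_depth * rim
        if ap.interior_texture > 0:
            # shift the texture with the (rounded) blob position
            shift = np.round(pos - centre).astype(int)
            tex = np.roll(np.roll(tex_grid, shift[0], axis=0), shift[1], axis=1)
            bf[mask] += tex[mask]
        frames[t] = np.clip(bf, 0.0, 1.2)
        masks[t] = mask

        for stack, value in ((her1, her1_sig[t]), (mesp, mesp_sig[t])):
            img = np.full((size, size), 0.02)
            img[mask] = value
            if ap.fluor_noise_sd > 0:
                img += rng.normal(0.0, ap.fluor_noise_sd, size=(size, size))
            stack[t] = img
    return SyntheticScene(frames=frames, masks=masks, her1_stack=her1,
                          mesp_stack=mesp, program=program, times=times,
                          frame_interval=preset.frame_interval)
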