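"""Synthetic facial-profile stand-in data.

Generates correlated 23-landmark configurations in a 1200x1200 space at
0.35 mm/px, renders toy grayscale profile images with a distinct local
texture at every landmark, and samples structured stage-1 localization noise
(a shared low-rank component plus independent jitter, with optional inflation
for the five off-curve "deep" landmarks).

The template is geometric rather than anatomically calibrated: 18 points lie
on a smooth curve monotone in y (the profile edge), 5 points sit off the
curve inside the head, and the y-spread exceeds the x-spread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    DEFAULT_MM_PER_PX,
    N_LANDMARKS,
    CropTransform,
    ImageSpace,
    LandmarkScheme,
    LandmarkSet,
)

TEMPLATE_SIDE = 1200
#: 1-based indices of the five off-curve landmarks (deep-structure analogues).
DEEP_INDICES: Tuple[int, ...] = (1, 8, 10, 13, 21)


class RenderError(ValueError):
    pass


def default_template() -> np.ndarray:
    """23 mean landmark positions (px) in the 1200x1200 template space."""
    coords = np.zeros((N_LANDMARKS, 2))
    curve_indices = [i for i in range(1, N_LANDMARKS + 1) if i not in DEEP_INDICES]
    ts = np.linspace(0.0, 1.0, len(curve_indices))
    for idx, t in zip(curve_indices, ts):
        y = 150.0 + 900.0 * t
        # forehead bulge, nose bump, lip/chin undulation
        x = (
            640.0
            + 70.0 * math.sin(math.pi * t)
            + 45.0 * math.sin(2.0 * math.pi * t * 2.1 + 0.4)
            + 25.0 * math.sin(2.0 * math.pi * t * 4.3)
        )
        coords[idx - 1] = (x, y)
    deep_positions = {
        1: (430.0, 270.0),
        8: (585.0, 1035.0),
        10: (430.0, 880.0),
        13: (380.0, 540.0),
        21: (470.0, 710.0),
    }
    for idx, xy in deep_positions.items():
        coords[idx - 1] = xy
    return coords


@dataclass
class ShapeModel:
    """Template + low-rank deformation modes + independent jitter."""

    template: np.ndarray
    modes: np.ndarray  # (k, 23, 2), unit Frobenius norm each
    mode_sds: np.ndarray  # (k,) standard deviations in px
    jitter_sd: float = 2.0
    margin: float = 40.0
    side: int = TEMPLATE_SIDE
    mm_per_px: float = DEFAULT_MM_PER_PX

    @classmethod
    def default(cls, k: int = 3, mode_sds: Sequence[float] = (14.0, 9.0, 6.0),
                jitter_sd: float = 2.0) -> "ShapeModel":
        rng = np.random.default_rng(20231116)
        modes = rng.standard_normal((k, N_LANDMARKS, 2))
        for m in modes:
            m /= np.linalg.norm(m)
        return cls(
            template=default_template(),
            modes=modes,
            mode_sds=np.asarray(mode_sds[:k], dtype=float),
            jitter_sd=jitter_sd,
        )

    @property
    def space(self) -> ImageSpace:
        return ImageSpace(self.side, self.side, mm_per_px=self.mm_per_px)


def sample_landmarks(
    model: ShapeModel, n: int, seed: int, scheme: Optional[LandmarkScheme] = None
) -> List[LandmarkSet]:
    """Draw n ground-truth landmark sets from the shape model (deterministic in seed)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    scheme = scheme or LandmarkScheme.default()
    space = model.space
    k = model.modes.shape[0]
    sets = []
    for _ in range(n):
        z = rng.standard_normal(k) * model.mode_sds
        jitter = rng.standard_normal((N_LANDMARKS, 2)) * model.jitter_sd
        coords = model.template + np.tensordot(z, model.modes, axes=1) + jitter
        np.clip(coords, model.margin, model.side - model.margin, out=coords)
        sets.append(LandmarkSet(scheme, space, coords, role="ground_truth"))
    return sets


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _stamp_params(index: int) -> Tuple[float, float, float]:
    """Deterministic per-landmark (sigma_px, amplitude, satellite angle)."""
    sigma = 1.3 + 0.9 * ((index * 37) % 7) / 6.0
    amp = 0.55 + 0.4 * ((index * 13) % 5) / 4.0
    angle = 2.0 * math.pi * index / N_LANDMARKS
    return sigma, amp, angle


def render_background(side: int, seed: int = 0) -> np.ndarray:
    yy = np.linspace(0.0, 1.0, side)[:, None]
    xx = np.linspace(0.0, 1.0, side)[None, :]
    img = 0.22 + 0.08 * yy + 0.04 * xx
    rng = np.random.default_rng(seed)
    img = img + 0.004 * rng.standard_normal((side, side))
    return np.clip(img, 0.0, 1.0)


def render_image(ls: LandmarkSet, side: Optional[int] = None, seed: int = 0) -> np.ndarray:
    """Render a grayscale image with a distinct blob pattern at each landmark.

    ``ls`` must already be expressed in the rendering space (``side`` defaults
    to the width of ``ls.space``).  Each landmark contributes a positive
    Gaussian blob centred on its coordinate plus a weaker satellite blob at a
    landmark-specific bearing, making the 23 local patterns distinguishable.
    """
    side = side or ls.space.width_px
    coords = ls.coords
    if np.any(coords < 0) or np.any(coords > side - 1):
        raise RenderError("landmark out of rendering bounds")
    img = render_background(side, seed=seed)
    yy = np.arange(side, dtype=float)[:, None]
    xx = np.arange(side, dtype=float)[None, :]
    for i, (cx, cy) in enumerate(coords, start=1):
        sigma, amp, angle = _stamp_params(i)
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        img += amp * np.exp(-d2 / (2.0 * sigma * sigma))
        sx = cx + 3.0 * sigma * math.cos(angle)
        sy = cy + 3.0 * sigma * math.sin(angle)
        d2s = (xx - sx) ** 2 + (yy - sy) ** 2
        img += 0.3 * amp * np.exp(-d2s / (2.0 * sigma * sigma))
    return np.clip(img, 0.0, 1.5)


# ---------------------------------------------------------------------------
# structured stage-1 noise
# ---------------------------------------------------------------------------

@dataclass
class NoiseModel:
    """Low-rank correlated error + independent per-landmark jitter (px)."""

    modes: np.ndarray  # (r, 23, 2), unit Frobenius norm each
    mode_sds: np.ndarray  # (r,)
    indep_sd: float = 1.0
    deep_inflation: float = 1.0  # multiplies indep_sd at DEEP_INDICES

    @classmethod
    def default(
        cls,
        rank: int = 2,
        mode_sds: Sequence[float] = (30.0, 18.0),
        indep_sd: float = 1.0,
        deep_inflation: float = 2.0,
        seed: int = 77,
    ) -> "NoiseModel":
        rng = np.random.default_rng(seed)
        modes = rng.standard_normal((rank, N_LANDMARKS, 2))
        for m in modes:
            m /= np.linalg.norm(m)
        return cls(modes=modes, mode_sds=np.asarray(mode_sds[:rank], dtype=float),
                   indep_sd=indep_sd, deep_inflation=deep_inflation)

    @classmethod
    def independent(cls, sd: float) -> "NoiseModel":
        return cls(
            modes=np.zeros((1, N_LANDMARKS, 2)),
            mode_sds=np.zeros(1),
            indep_sd=sd,
            deep_inflation=1.0,
        )

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal(self.modes.shape[0]) * self.mode_sds
        err = np.tensordot(z, self.modes, axes=1)
        indep = rng.standard_normal((N_LANDMARKS, 2)) * self.indep_sd
        if self.deep_inflation != 1.0:
            for idx in DEEP_INDICES:
                indep[idx - 1] *= self.deep_inflation
        return err + indep


def corrupt(ls: LandmarkSet, noise: NoiseModel, seed: int) -> LandmarkSet:
    """Apply structured stage-1-like noise to a ground-truth set."""
    rng = np.random.default_rng(seed)
    return LandmarkSet(ls.scheme, ls.space, ls.coords + noise.sample(rng), role="stage1")


def corrupt_many(sets: Sequence[LandmarkSet], noise: NoiseModel, seed: int) -> List[LandmarkSet]:
    rng = np.random.default_rng(seed)
    return [
        LandmarkSet(s.scheme, s.space, s.coords + noise.sample(rng), role="stage1")
        for s in sets
    ]


# ---------------------------------------------------------------------------
# rendered dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Rendered images in model-input space + ground truth in template space."""

    images: np.ndarray  # (n, side, side) float in [0, 1.5]
    gt: List[LandmarkSet]  # in the original template space
    crop: CropTransform  # template space -> input space
    input_side: int
    seed: int

    @property
    def n(self) -> int:
        return self.images.shape[0]

    def target_maps(self, sigma: float, normalized: bool = False,
                    reduction: int = 4) -> np.ndarray:
        from .heatmaps import encode

        side = self.input_side // reduction
        out = np.empty((self.n, N_LANDMARKS, side, side))
        for i, ls in enumerate(self.gt):
            out[i] = encode(
                ls, sigma=sigma, grid_shape=(side, side), reduction=reduction,
                crop=self.crop, normalized=normalized,
            ).maps
        return out


def make_dataset(
    n: int,
    input_side: int = 64,
    seed: int = 0,
    shape_model: Optional[ShapeModel] = None,
) -> SyntheticDataset:
    """Sample, project and render a full synthetic dataset."""
    model = shape_model or ShapeModel.default()
    gt = sample_landmarks(model, n, seed)
    crop = CropTransform.full_frame(model.space, target_side=input_side)
    images = np.empty((n, input_side, input_side))
    input_space = ImageSpace(input_side, input_side, mm_per_px=None)
    for i, ls in enumerate(gt):
        mapped = LandmarkSet(ls.scheme, input_space, crop.map(ls.coords), role="ground_truth")
        images[i] = render_image(mapped, side=input_side, seed=seed * 100003 + i)
    return SyntheticDataset(images=images, gt=gt, crop=crop, input_side=input_side, seed=seed)
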