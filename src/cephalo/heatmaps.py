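"""Gaussian heatmap encoding and sub-pixel argmax decoding.

Each landmark is encoded as an isotropic 2D Gaussian centred on its mapped
position in a reduced-resolution grid.  Decoding takes the per-channel argmax
and, when enabled, nudges the estimate 0.25 heatmap pixels along each axis
toward the larger of the two axis neighbours before mapping the position back
to the original image space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .core import (
    N_LANDMARKS,
    ContractError,
    CropTransform,
    ImageSpace,
    LandmarkScheme,
    LandmarkSet,
)

DEFAULT_SIGMA = 1.5  # heatmap pixels
DEFAULT_REDUCTION = 4


class ParameterError(ValueError):
    pass


class DecodeError(ValueError):
    """A heatmap channel has no strict structure to decode (all values equal)."""


@dataclass
class HeatmapStack:
    """23 reduced-resolution maps plus the metadata needed to invert them.

    ``maps`` has shape (23, h, w).  A heatmap pixel (px, py) corresponds to
    model-input coordinate (px * reduction, py * reduction) under the
    pixel-center model; ``crop`` (optional) maps original-image coordinates to
    model-input coordinates.
    """

    maps: np.ndarray
    sigma: float
    reduction: int = DEFAULT_REDUCTION
    crop: Optional[CropTransform] = None

    def __post_init__(self) -> None:
        maps = np.asarray(self.maps, dtype=float)
        if maps.ndim != 3 or maps.shape[0] != N_LANDMARKS:
            raise ContractError(
                f"maps must have shape ({N_LANDMARKS}, h, w), got {maps.shape}"
            )
        if not np.all(np.isfinite(maps)):
            raise ContractError("heatmap values must be finite")
        self.maps = maps

    @property
    def grid_shape(self) -> Tuple[int, int]:
        return self.maps.shape[1], self.maps.shape[2]  # (h, w)


def landmarks_to_heatmap_coords(ls: LandmarkSet, reduction: int,
                                crop: Optional[CropTransform]) -> np.ndarray:
    xy = ls.coords
    if crop is not None:
        xy = crop.map(xy)
    return xy / reduction


def encode(
    ls: LandmarkSet,
    sigma: float = DEFAULT_SIGMA,
    grid_shape: Tuple[int, int] = (64, 64),
    reduction: int = DEFAULT_REDUCTION,
    crop: Optional[CropTransform] = None,
    normalized: bool = True,
) -> HeatmapStack:
    """Encode a landmark set as a stack of Gaussian heatmaps.

    With ``normalized=True`` each channel is the bivariate normal density
    ``(1 / (2 pi sigma^2)) exp(-||x - L||^2 / (2 sigma^2))``; otherwise the
    peak-1 variant drops the normalizing constant.  Landmarks outside the
    grid produce a truncated Gaussian tail rather than an error.
    """
    if not sigma > 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    h, w = grid_shape
    centers = landmarks_to_heatmap_coords(ls, reduction, crop)
    yy = np.arange(h, dtype=float)[:, None]
    xx = np.arange(w, dtype=float)[None, :]
    maps = np.empty((N_LANDMARKS, h, w), dtype=float)
    two_s2 = 2.0 * sigma * sigma
    scale = 1.0 / (2.0 * math.pi * sigma * sigma) if normalized else 1.0
    for i, (cx, cy) in enumerate(centers):
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        maps[i] = scale * np.exp(-d2 / two_s2)
    return HeatmapStack(maps=maps, sigma=sigma, reduction=reduction, crop=crop)


def _argmax_with_offset(channel: np.ndarray, use_offset: bool, index: int) -> Tuple[float, float]:
    h, w = channel.shape
    flat = int(np.argmax(channel))  # row-major first occurrence on ties
    peak = channel.flat[flat]
    if peak == channel.flat[0] and np.all(channel == peak):
        raise DecodeError(f"channel {index}: all heatmap values are equal; nothing to decode")
    py, px = divmod(flat, w)
    x, y = float(px), float(py)
    if use_offset:
        if 0 < px < w - 1:
            left, right = channel[py, px - 1], channel[py, px + 1]
            if right > left:
                x += 0.25
            elif left > right:
                x -= 0.25
        if 0 < py < h - 1:
            up, down = channel[py - 1, px], channel[py + 1, px]
            if down > up:
                y += 0.25
            elif up > down:
                y -= 0.25
    return x, y


def decode(
    hs: HeatmapStack,
    scheme: LandmarkScheme,
    space: ImageSpace,
    offset: bool = True,
) -> LandmarkSet:
    """Decode a heatmap stack to a stage-1 landmark set in ``space``.

    Per channel: argmax (ties broken row-major), optional quarter-pixel shift
    along each axis toward the larger neighbour (no shift on borders or exact
    ties), then the heatmap -> model-input scaling and the inverse crop.
    """
    coords_hm = np.array(
        [_argmax_with_offset(hs.maps[i], offset, i + 1) for i in range(N_LANDMARKS)],
        dtype=float,
    )
    coords_in = coords_hm * hs.reduction
    coords = hs.crop.unmap(coords_in) if hs.crop is not None else coords_in
    return LandmarkSet(scheme=scheme, space=space, coords=coords, role="stage1")


def heatmap_l2_loss(gt: HeatmapStack, pred: HeatmapStack) -> float:
    """Sum over channels of squared element-wise heatmap differences."""
    if gt.maps.shape != pred.maps.shape:
        raise ContractError(
            f"heatmap shape mismatch: {gt.maps.shape} vs {pred.maps.shape}"
        )
    diff = gt.maps - pred.maps
    return float(np.sum(diff * diff))
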