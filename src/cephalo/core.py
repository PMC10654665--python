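"""Domain types and geometric primitives for 23-point facial-profile landmark sets.

Coordinate conventions used throughout the package:

* origin at the top-left of the image, x increasing rightward, y downward;
* coordinates are real-valued pixels under a pixel-center model, i.e.
  ``(0.0, 0.0)`` is the *center* of the top-left pixel;
* physical units are derived from ``ImageSpace.mm_per_px`` (0.35 mm/px for
  the reference acquisition device).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

N_LANDMARKS = 23
DEFAULT_MM_PER_PX = 0.35

#: Index -> anatomical alias for the landmarks whose identity is fixed by the
#: clinical measure definitions.  All other indices are positional only and
#: may be renamed by the user.
DEFAULT_ALIASES: dict[int, str] = {
    1: "Sella",
    2: "Nasion",
    5: "A-point",
    6: "B-point",
    8: "Menton",
    10: "Gonion",
}

ROLES = ("ground_truth", "stage1", "refined")


class GeometryError(ValueError):
    """Degenerate geometric input (coincident points, zero-length line)."""


class UnitError(ValueError):
    """A physical-unit conversion was requested without a pixel spacing."""


class ContractError(ValueError):
    """Mismatched schemes, spaces or array shapes between two arguments."""


@dataclass(frozen=True)
class LandmarkScheme:
    """An ordered collection of landmark labels.

    Indices are 1-based externally (``L1`` .. ``L23``) and contiguous.
    """

    names: Tuple[str, ...]
    aliases: Tuple[Tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if len(self.names) != N_LANDMARKS:
            raise ContractError(
                f"scheme must have exactly {N_LANDMARKS} landmarks, got {len(self.names)}"
            )
        if len(set(self.names)) != len(self.names):
            raise ContractError("landmark names must be unique")

    @property
    def count(self) -> int:
        return len(self.names)

    @classmethod
    def default(cls) -> "LandmarkScheme":
        names = tuple(f"L{i}" for i in range(1, N_LANDMARKS + 1))
        return cls(names=names, aliases=tuple(sorted(DEFAULT_ALIASES.items())))

    def name_of(self, index: int) -> str:
        """Label for a 1-based landmark index."""
        if not 1 <= index <= self.count:
            raise IndexError(f"landmark index {index} out of range 1..{self.count}")
        return self.names[index - 1]

    def alias_of(self, index: int) -> Optional[str]:
        for i, alias in self.aliases:
            if i == index:
                return alias
        return None


@dataclass(frozen=True)
class ImageSpace:
    """A pixel grid with an optional physical pixel spacing."""

    width_px: int
    height_px: int
    mm_per_px: Optional[float] = DEFAULT_MM_PER_PX

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ContractError("image dimensions must be >= 1 pixel")
        if self.mm_per_px is not None and not self.mm_per_px > 0:
            raise ContractError("mm_per_px must be positive")

    def require_spacing(self) -> float:
        if self.mm_per_px is None:
            raise UnitError("this ImageSpace has no mm_per_px; cannot convert to mm")
        return self.mm_per_px


def default_space(side: int = 1200, mm_per_px: float = DEFAULT_MM_PER_PX) -> ImageSpace:
    return ImageSpace(width_px=side, height_px=side, mm_per_px=mm_per_px)


@dataclass
class LandmarkSet:
    """23 named points in a declared coordinate space, tagged with a role."""

    scheme: LandmarkScheme
    space: ImageSpace
    coords: np.ndarray  # (23, 2) float, columns (x, y)
    role: str = "ground_truth"

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (N_LANDMARKS, 2):
            raise ContractError(
                f"coords must have shape ({N_LANDMARKS}, 2), got {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise ContractError("all landmark coordinates must be finite")
        if self.role not in ROLES:
            raise ContractError(f"role must be one of {ROLES}, got {self.role!r}")
        self.coords = coords

    def point(self, index: int) -> np.ndarray:
        """Coordinate pair for a 1-based landmark index."""
        if not 1 <= index <= N_LANDMARKS:
            raise IndexError(f"landmark index {index} out of range 1..{N_LANDMARKS}")
        return self.coords[index - 1]

    def with_role(self, role: str) -> "LandmarkSet":
        return LandmarkSet(self.scheme, self.space, self.coords.copy(), role)

    def with_coords(self, coords: np.ndarray, role: Optional[str] = None) -> "LandmarkSet":
        return LandmarkSet(self.scheme, self.space, coords, role or self.role)

    def to_mm(self, delta: "np.ndarray | float") -> "np.ndarray | float":
        """Convert a pixel displacement measured in this space to millimetres."""
        return to_mm(self, delta)


def to_mm(ls: LandmarkSet, delta: "np.ndarray | float") -> "np.ndarray | float":
    """Convert a pixel displacement to millimetres using the set's pixel spacing."""
    spacing = ls.space.require_spacing()
    return np.asarray(delta, dtype=float) * spacing if np.ndim(delta) else float(delta) * spacing


@dataclass(frozen=True)
class CropTransform:
    """Isotropic scale + offset mapping from a source to a target pixel space.

    ``map``:  (x, y) -> ((x - x0) * scale, (y - y0) * scale)
    ``unmap`` is the exact inverse.  Round-tripping is identity to ~1e-9 px.
    """

    scale: float
    x0: float = 0.0
    y0: float = 0.0
    target: Optional[ImageSpace] = None

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ContractError("CropTransform scale must be positive")

    def map(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        return (xy - np.array([self.x0, self.y0])) * self.scale

    def unmap(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        return xy / self.scale + np.array([self.x0, self.y0])

    @classmethod
    def full_frame(cls, source: ImageSpace, target_side: int = 256) -> "CropTransform":
        """Center full-frame resize of a square source image to ``target_side``."""
        side = max(source.width_px, source.height_px)
        return cls(
            scale=target_side / side,
            x0=0.0,
            y0=0.0,
            target=ImageSpace(target_side, target_side, mm_per_px=None),
        )


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------

def _as_vec(p) -> np.ndarray:
    v = np.asarray(p, dtype=float)
    if v.shape != (2,):
        raise ContractError(f"expected a 2D point, got shape {v.shape}")
    return v


def angle_at_vertex(a, v, b) -> float:
    """Unsigned angle in degrees at vertex ``v`` between rays v->a and v->b.

    Result lies in [0, 180].  Raises :class:`GeometryError` if either ray is
    degenerate (``a == v`` or ``b == v``).
    """
    a, v, b = _as_vec(a), _as_vec(v), _as_vec(b)
    u1 = a - v
    u2 = b - v
    n1 = math.hypot(*u1)
    n2 = math.hypot(*u2)
    if n1 == 0.0 or n2 == 0.0:
        raise GeometryError("angle_at_vertex: a ray endpoint coincides with the vertex")
    dot = float(u1 @ u2)
    cross = float(u1[0] * u2[1] - u1[1] * u2[0])
    return math.degrees(math.atan2(abs(cross), dot))


def angle_between_lines(p1, p2, q1, q2, signed: bool = False) -> float:
    """Angle in degrees between the (infinite) lines p1-p2 and q1-q2.

    Unsigned mode returns the acute angle in [0, 90].  Signed mode returns an
    angle in (-90, 90] measured as the rotation carrying the oriented line
    p1->p2 onto q1->q2, with positive sign for a counterclockwise rotation in
    the image coordinate frame (x right, y down).
    """
    d1 = _as_vec(p2) - _as_vec(p1)
    d2 = _as_vec(q2) - _as_vec(q1)
    if math.hypot(*d1) == 0.0 or math.hypot(*d2) == 0.0:
        raise GeometryError("angle_between_lines: zero-length line")
    dot = float(d1 @ d2)
    cross = float(d1[0] * d2[1] - d1[1] * d2[0])
    theta = math.degrees(math.atan2(cross, dot))  # (-180, 180]
    # Lines are direction-free: fold onto (-90, 90].
    while theta <= -90.0:
        theta += 180.0
    while theta > 90.0:
        theta -= 180.0
    return abs(theta) if not signed else theta


def distance(p, q, space: Optional[ImageSpace] = None, unit: str = "px") -> float:
    """Euclidean distance between two points, in pixels or millimetres."""
    p, q = _as_vec(p), _as_vec(q)
    d = float(math.hypot(*(p - q)))
    if unit == "px":
        return d
    if unit == "mm":
        if space is None:
            raise UnitError("distance in mm requires an ImageSpace with mm_per_px")
        return d * space.require_spacing()
    raise ValueError(f"unknown unit {unit!r}; expected 'px' or 'mm'")


def check_compatible(a: LandmarkSet, b: LandmarkSet) -> None:
    """Raise :class:`ContractError` unless two sets share scheme and space."""
    if a.scheme.names != b.scheme.names:
        raise ContractError("landmark sets use different schemes")
    if (a.space.width_px, a.space.height_px, a.space.mm_per_px) != (
        b.space.width_px,
        b.space.height_px,
        b.space.mm_per_px,
    ):
        raise ContractError("landmark sets live in different image spaces")
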