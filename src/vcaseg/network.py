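"""Vascular connectivity analysis: starting points, gap-tolerant growth, rotations.

The network is grown from detected starting points by repeatedly admitting
every "effective" pixel (intensity at or above a threshold) lying within a
Euclidean distance ``d_max`` of the current set — a 2-px tolerance lets the
growth bridge small flow dropouts without flooding the background. Raster
sweeps are iterated to a fixed point, so a single run is order-independent;
the procedure is still repeated under 90-degree rotations of the image and
the four results merged, which also makes the output rotation-equivariant by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import ndimage

from .errors import BoundsError, DegenerateImageError, ShapeError, ValidationError

Coord = tuple[int, int]


class PixelSet:
    """Set of (row, col) pixels inside a host image, backed by a boolean mask."""

    __slots__ = ("_mask",)

    def __init__(self, mask: np.ndarray):
        m = np.asarray(mask)
        if m.ndim != 2:
            raise ShapeError(f"PixelSet mask must be 2-D, got shape {m.shape}")
        self._mask = m.astype(bool)

    @classmethod
    def from_points(cls, points: Iterable[Coord], shape: tuple[int, int]) -> "PixelSet":
        mask = np.zeros(shape, dtype=bool)
        for r, c in points:
            if not (0 <= r < shape[0] and 0 <= c < shape[1]):
                raise BoundsError(f"point ({r}, {c}) outside image of shape {shape}")
            mask[r, c] = True
        return cls(mask)

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "PixelSet":
        return cls(np.zeros(shape, dtype=bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self._mask.shape

    @property
    def points(self) -> frozenset[Coord]:
        rr, cc = np.nonzero(self._mask)
        return frozenset(zip(rr.tolist(), cc.tolist()))

    def to_mask(self) -> np.ndarray:
        return self._mask.copy()

    def union(self, other: "PixelSet") -> "PixelSet":
        if other.shape != self.shape:
            raise ShapeError("cannot union PixelSets with different shapes")
        return PixelSet(self._mask | other._mask)

    def issubset(self, other: "PixelSet") -> bool:
        return bool(np.all(~self._mask | other._mask))

    def __len__(self) -> int:
        return int(self._mask.sum())

    def __contains__(self, point: Coord) -> bool:
        r, c = point
        return 0 <= r < self.shape[0] and 0 <= c < self.shape[1] and bool(self._mask[r, c])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, PixelSet)
            and self.shape == other.shape
            and bool(np.array_equal(self._mask, other._mask))
        )

    def __hash__(self):  # mutable-array backed; not hashable
        raise TypeError("PixelSet is not hashable")

    def __repr__(self) -> str:
        return f"PixelSet({len(self)} points, shape={self.shape})"


@dataclass(frozen=True)
class StartPointParams:
    """Knobs of the probe-line ("partial line detection") starting-point test.

    A pixel is *effective* if its intensity is at or above
    ``effective_intensity`` (``None`` means: use the Otsu threshold of the
    ROI). Around each effective pixel, ``n_directions`` centered probe lines
    of ``line_length`` pixels are examined; a line is *empty* when it holds
    no effective pixel besides (possibly) the center. The pixel is a
    starting point iff the fraction of empty lines is strictly below
    ``empty_line_proportion_max``.
    """

    line_length: int = 7
    n_directions: int = 4
    effective_intensity: float | None = None
    empty_line_proportion_max: float = 0.5

    def __post_init__(self) -> None:
        if self.line_length < 3 or self.line_length % 2 == 0:
            raise ValidationError(f"line_length must be odd and >= 3, got {self.line_length}")
        if self.n_directions not in (2, 4, 8):
            raise ValidationError(f"n_directions must be 2, 4, or 8, got {self.n_directions}")
        if not 0.0 <= self.empty_line_proportion_max <= 1.0:
            raise ValidationError("empty_line_proportion_max must lie in [0, 1]")
        if self.effective_intensity is not None and not 0.0 <= self.effective_intensity <= 1.0:
            raise ValidationError("effective_intensity must lie in [0, 1]")


@dataclass(frozen=True)
class GrowthParams:
    """Admission rule for connectivity growth: Euclidean distance <= d_max."""

    d_max: float = 2.0
    effective_intensity: float | None = None

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValidationError(f"d_max must be positive, got {self.d_max}")
        if self.effective_intensity is not None and not 0.0 <= self.effective_intensity <= 1.0:
            raise ValidationError("effective_intensity must lie in [0, 1]")


# Probe-line orientations as (dr, dc) steps; a line uses both the step and
# its negation, so each entry is one orientation.
_ORIENTATIONS = {
    2: [(0, 1), (1, 0)],
    4: [(0, 1), (1, 0), (1, 1), (1, -1)],
    8: [(0, 1), (1, 0), (1, 1), (1, -1), (1, 2), (2, 1), (2, -1), (1, -2)],
}


def _effective(img: np.ndarray, threshold: float) -> np.ndarray:
    a = np.asarray(img, dtype=np.float64)
    if a.ndim != 2:
        raise ShapeError(f"expected a 2-D image, got shape {a.shape}")
    return a >= threshold


def _resolve_threshold(img: np.ndarray, value: float | None) -> float:
    if value is not None:
        return float(value)
    from .binarization import otsu_threshold  # local import: avoid cycle

    return otsu_threshold(img)


def _line_kernel(step: Coord, half: int) -> np.ndarray:
    """Binary kernel of the 2*half off-center pixels of one centered probe line."""
    dr, dc = step
    hr, hc = half * abs(dr), half * abs(dc)
    kernel = np.zeros((2 * hr + 1, 2 * hc + 1), dtype=np.uint8)
    for j in range(-half, half + 1):
        if j != 0:
            kernel[hr + j * dr, hc + j * dc] = 1
    return kernel


def detect_starting_points(
    img: np.ndarray,
    params: StartPointParams = StartPointParams(),
    threshold: float | None = None,
) -> PixelSet:
    """Scan the image boustrophedon-style and keep pixels passing the line test.

    The Z-shaped (boustrophedon) traversal order does not alter the result —
    the test is per-pixel — so the scan is evaluated vectorized. Pixels whose
    probe lines extend beyond the border treat outside positions as not
    effective. An image with no effective pixels yields an empty set.
    """
    thr = threshold if threshold is not None else params.effective_intensity
    try:
        thr = _resolve_threshold(img, thr)
    except DegenerateImageError:
        return PixelSet.empty(np.asarray(img).shape)  # constant image: nothing effective
    eff = _effective(img, thr)
    if not eff.any():
        return PixelSet.empty(eff.shape)

    half = (params.line_length - 1) // 2
    eff_u8 = eff.astype(np.uint8)
    n_empty = np.zeros(eff.shape, dtype=np.int32)
    for step in _ORIENTATIONS[params.n_directions]:
        counts = ndimage.correlate(eff_u8, _line_kernel(step, half), mode="constant", cval=0)
        n_empty += counts == 0
    is_start = eff & (n_empty / params.n_directions < params.empty_line_proportion_max)
    return PixelSet(is_start)


def growth_footprint(d_max: float) -> np.ndarray:
    """Binary structuring element of all offsets within Euclidean d_max."""
    r = int(math.floor(d_max))
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    return (dr * dr + dc * dc) <= d_max * d_max + 1e-12


def grow_network(
    img: np.ndarray,
    starts: PixelSet,
    params: GrowthParams = GrowthParams(),
    threshold: float | None = None,
) -> PixelSet:
    """Closure of the starting points under the <= d_max admission rule.

    Full-image sweeps are iterated until a fixed point: each sweep admits
    every effective pixel within ``d_max`` of the current set. The result is
    exactly the breadth-first closure of ``starts`` over effective pixels
    with that adjacency (the fixed point is unique), and always contains
    ``starts``. The sweep count is hard-bounded by the pixel count.
    """
    a = np.asarray(img, dtype=np.float64)
    if starts.shape != a.shape:
        raise ShapeError(f"starts shape {starts.shape} != image shape {a.shape}")
    if len(starts) == 0:
        return PixelSet.empty(a.shape)
    thr = _resolve_threshold(a, threshold if threshold is not None else params.effective_intensity)
    eff = _effective(a, thr)
    fp = growth_footprint(params.d_max)

    current = starts.to_mask()
    admissible = eff | current  # starts stay in even if not effective themselves
    for _ in range(current.size):
        grown = ndimage.binary_dilation(current, structure=fp) & admissible
        if np.array_equal(grown, current):
            break
        current = grown
    return PixelSet(current)


def rotate_image(img: np.ndarray, quarter_turns: int) -> tuple[np.ndarray, "RotationMap"]:
    """Rotate by 90-degree multiples (counter-clockwise) with a coordinate map back.

    Only quarter turns are supported: they are lossless bijections, which the
    merge step relies on. The returned :class:`RotationMap` sends every
    rotated-frame coordinate (or mask) to the original frame.
    """
    if quarter_turns not in (0, 1, 2, 3):
        raise ValidationError(f"quarter_turns must be 0..3, got {quarter_turns}")
    a = np.asarray(img)
    return np.rot90(a, quarter_turns), RotationMap(quarter_turns, a.shape[:2])


@dataclass(frozen=True)
class RotationMap:
    """Bijection from the rotated frame back to the original R x C frame.

    With numpy's counter-clockwise convention, one quarter turn maps rotated
    (r', c') to original (c', C - 1 - r').
    """

    quarter_turns: int
    original_shape: tuple[int, int]

    def to_original(self, r: int, c: int) -> Coord:
        rows, cols = self.original_shape
        k = self.quarter_turns % 4
        if k == 0:
            return r, c
        if k == 1:
            return c, cols - 1 - r
        if k == 2:
            return rows - 1 - r, cols - 1 - c
        return rows - 1 - c, r

    def mask_to_original(self, mask: np.ndarray) -> np.ndarray:
        out = np.rot90(np.asarray(mask), -self.quarter_turns)
        if out.shape[:2] != self.original_shape:
            raise ShapeError("mask does not belong to this rotation's frame")
        return out

    def pixelset_to_original(self, ps: PixelSet) -> PixelSet:
        return PixelSet(self.mask_to_original(ps.to_mask()))


def extract_network(
    img: np.ndarray,
    sp: StartPointParams = StartPointParams(),
    gp: GrowthParams = GrowthParams(),
    threshold: float | None = None,
) -> PixelSet:
    """Detect + grow under all four quarter-turn rotations and merge.

    The effective-intensity threshold is resolved once on the unrotated
    image (the histogram is rotation-invariant) so all four runs agree.
    """
    a = np.asarray(img, dtype=np.float64)
    thr = threshold if threshold is not None else sp.effective_intensity
    try:
        thr = _resolve_threshold(a, thr)
    except DegenerateImageError:
        return PixelSet.empty(a.shape)
    merged = PixelSet.empty(a.shape)
    for k in range(4):
        rot, rmap = rotate_image(a, k)
        starts = detect_starting_points(rot, sp, threshold=thr)
        grown = grow_network(rot, starts, gp, threshold=thr)
        merged = merged.union(rmap.pixelset_to_original(grown))
    return merged
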