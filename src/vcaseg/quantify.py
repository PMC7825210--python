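"""Vessel morphometry: cumulative length, area, and width.

Length and area are plain pixel accumulations — the skeleton pixel count and
the mask pixel count of the surviving components — and width is their ratio
area / length. Counting pixels (rather than Euclidean arc length) keeps the
two accumulations on the same footing; a diagonal-weighted length is
available behind a flag for sensitivity checks but is not the default.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from .errors import ConsistencyError, ValidationError
from .skeleton import SkeletonGraph


@dataclass(frozen=True)
class VesselMetrics:
    """Morphometry of one image: length (px), area (px^2), width (px)."""

    length_px: float
    area_px2: int
    width_px: float
    defined: bool

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def measure(
    skeleton: np.ndarray,
    mask: np.ndarray,
    *,
    diagonal_weighted: bool = False,
    graph: "SkeletonGraph | None" = None,
) -> VesselMetrics:
    """Pixel-accumulation morphometry of a skeleton/mask pair.

    ``skeleton`` must be a subset of ``mask`` (both from the surviving
    components). With ``diagonal_weighted=True`` the length instead sums
    branch steps with sqrt(2) for diagonal moves, which requires ``graph``.
    """
    sk = np.asarray(skeleton, dtype=bool)
    m = np.asarray(mask, dtype=bool)
    if sk.shape != m.shape:
        raise ConsistencyError(f"skeleton shape {sk.shape} != mask shape {m.shape}")
    if np.any(sk & ~m):
        raise ConsistencyError("skeleton is not a subset of the mask")

    if diagonal_weighted:
        if graph is None:
            raise ValidationError("diagonal_weighted length requires the skeleton graph")
        length = diagonal_weighted_length(graph)
    else:
        length = float(sk.sum())
    area = int(m.sum())
    if length > 0:
        return VesselMetrics(length, area, area / length, True)
    return VesselMetrics(0.0, area, float("nan"), False)


def diagonal_weighted_length(graph: SkeletonGraph) -> float:
    """Arc-length variant: 1 per axial step, sqrt(2) per diagonal step."""
    total = 0.0
    for comp in graph.components:
        for br in comp.branches:
            if len(br.pixels) == 1:
                total += 1.0
                continue
            for (r0, c0), (r1, c1) in zip(br.pixels[:-1], br.pixels[1:]):
                total += math.sqrt(2.0) if (r0 != r1 and c0 != c1) else 1.0
    return total


def percent_change(reference: float, current: float) -> float:
    """Signed percent change relative to ``reference`` (negative = reduction)."""
    if reference <= 0:
        raise ValidationError(f"reference must be positive, got {reference}")
    return (current - reference) / reference * 100.0


def percent_of_reference(reference: float, current: float) -> float:
    """``current`` expressed as a percentage of ``reference``."""
    if reference <= 0:
        raise ValidationError(f"reference must be positive, got {reference}")
    return current / reference * 100.0
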