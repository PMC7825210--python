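"""Flat namespaced key=value configuration for the pipeline.

Every tunable of the segmentation stages lives under a namespaced key
(``start.*``, ``grow.*``, ``binarize.*``, ``filter.*``, ``quantify.*``,
``stats.*``, ``io.*``, ``run.*``). Files are plain ``key = value`` lines
('#' starts a comment); CLI flags override file values. Unknown keys are
rejected up front so typos never silently fall back to defaults.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Any

from .errors import ValidationError
from .image_io import RectROI
from .network import GrowthParams, StartPointParams
from .skeleton import FilterParams


def _parse_scalar(text: str) -> Any:
    t = text.strip()
    low = t.lower()
    if low in ("none", "null", ""):
        return None
    if low in ("true", "false"):
        return low == "true"
    if low == "otsu":
        return "otsu"
    try:
        return int(t)
    except ValueError:
        pass
    try:
        return float(t)
    except ValueError:
        return t


@dataclass
class PipelineConfig:
    """All pipeline tunables, addressable by namespaced key."""

    start_line_length: int = 7
    start_n_directions: int = 4
    start_empty_line_proportion_max: float = 0.5
    effective_intensity: Any = "otsu"  # "otsu" or a float in [0, 1]
    grow_d_max: float = 2.0
    binarize_n_bins: int = 256
    binarize_manual_threshold: float | None = None
    binarize_fill_holes_max_area: int = 10
    filter_min_branch_length: int = 5
    filter_min_ratio: float = 3.0
    quantify_diagonal_weighted: bool = False
    stats_day_reference: int = 1
    stats_day_final: int = 7
    stats_paired: bool = False
    io_roi: tuple[int, int, int, int] | None = None  # top,left,height,width
    io_calibration_mm_per_px: float | None = None
    run_seed: int = 0
    run_log_level: str = "INFO"

    _KEYMAP = {
        "start.line_length": "start_line_length",
        "start.n_directions": "start_n_directions",
        "start.empty_line_proportion_max": "start_empty_line_proportion_max",
        "effective_intensity": "effective_intensity",
        "grow.d_max": "grow_d_max",
        "binarize.n_bins": "binarize_n_bins",
        "binarize.manual_threshold": "binarize_manual_threshold",
        "binarize.fill_holes_max_area": "binarize_fill_holes_max_area",
        "filter.min_branch_length": "filter_min_branch_length",
        "filter.min_ratio": "filter_min_ratio",
        "quantify.diagonal_weighted": "quantify_diagonal_weighted",
        "stats.day_reference": "stats_day_reference",
        "stats.day_final": "stats_day_final",
        "stats.paired": "stats_paired",
        "io.roi": "io_roi",
        "io.calibration_mm_per_px": "io_calibration_mm_per_px",
        "run.seed": "run_seed",
        "run.log_level": "run_log_level",
    }

    @classmethod
    def from_items(cls, items: dict[str, Any]) -> "PipelineConfig":
        cfg = cls()
        cfg.update(items)
        return cfg

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "PipelineConfig":
        items: dict[str, Any] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"config line is not key=value: {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            items[key] = value
        return cls.from_items(items)

    def update(self, items: dict[str, Any]) -> None:
        for key, value in items.items():
            if key not in self._KEYMAP:
                raise ValidationError(f"unknown config key: {key!r}")
            attr = self._KEYMAP[key]
            if key == "io.roi" and isinstance(value, str):
                if value.strip().lower() in ("none", "null", ""):
                    value = None
                else:
                    parts = [p for p in value.replace(",", " ").split() if p]
                    if len(parts) != 4:
                        raise ValidationError("io.roi needs 4 integers: top,left,height,width")
                    value = tuple(int(p) for p in parts)
            elif isinstance(value, str):
                value = _parse_scalar(value)
            setattr(self, attr, value)
        self.validate()

    def validate(self) -> None:
        # Constructing the parameter objects runs every module's invariants.
        self.start_params()
        self.growth_params()
        self.filter_params()
        if self.binarize_n_bins < 2:
            raise ValidationError("binarize.n_bins must be >= 2")
        if self.binarize_fill_holes_max_area < 0:
            raise ValidationError("binarize.fill_holes_max_area must be >= 0")
        if self.binarize_manual_threshold is not None and not (
            0.0 <= self.binarize_manual_threshold <= 1.0
        ):
            raise ValidationError("binarize.manual_threshold must lie in [0, 1]")
        if self.io_roi is not None:
            RectROI(*self.io_roi)
        if self.io_calibration_mm_per_px is not None and self.io_calibration_mm_per_px <= 0:
            raise ValidationError("io.calibration_mm_per_px must be positive")

    def _effective(self) -> float | None:
        return None if self.effective_intensity == "otsu" else float(self.effective_intensity)

    def start_params(self) -> StartPointParams:
        return StartPointParams(
            line_length=self.start_line_length,
            n_directions=self.start_n_directions,
            effective_intensity=self._effective(),
            empty_line_proportion_max=self.start_empty_line_proportion_max,
        )

    def growth_params(self) -> GrowthParams:
        return GrowthParams(d_max=self.grow_d_max, effective_intensity=self._effective())

    def filter_params(self) -> FilterParams:
        return FilterParams(
            min_branch_length=self.filter_min_branch_length,
            min_length_per_node_ratio=self.filter_min_ratio,
        )

    def roi(self) -> RectROI | None:
        return RectROI(*self.io_roi) if self.io_roi is not None else None

    def to_items(self) -> dict[str, Any]:
        return {key: getattr(self, attr) for key, attr in self._KEYMAP.items()}

    def dump(self) -> str:
        lines = []
        for key, value in self.to_items().items():
            if isinstance(value, tuple):
                value = ",".join(str(v) for v in value)
            lines.append(f"{key} = {value}")
        return "\n".join(lines) + "\n"
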