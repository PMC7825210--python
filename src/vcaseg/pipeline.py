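"""End-to-end segmentation: the stages of the improved connectivity analysis.

One call runs crop/gray pre-processing, starting-point detection and
gap-tolerant growth under four rotations, Otsu binarization restricted to
the grown network, skeletonization, the piece-by-piece artifact filter, and
pixel-accumulation morphometry, keeping every intermediate for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.morphology import remove_small_holes

from . import binarization, image_io, network, quantify, skeleton
from .config import PipelineConfig
from .errors import DegenerateImageError
from .quantify import VesselMetrics
from .skeleton import SkeletonGraph


@dataclass
class SegmentationResult:
    """All intermediates of one segmentation run."""

    gray: np.ndarray
    network: network.PixelSet
    binary: np.ndarray
    skeleton_raw: np.ndarray
    graph_raw: SkeletonGraph
    graph_filtered: SkeletonGraph
    mask_final: np.ndarray
    metrics: VesselMetrics
    component_table: pd.DataFrame
    effective_threshold: float | None
    binarize_threshold: float | None

    @property
    def skeleton_filtered(self) -> np.ndarray:
        return self.graph_filtered.skeleton


def segment(img: np.ndarray, config: PipelineConfig | None = None) -> SegmentationResult:
    """Run the full segmentation on a normalized [0, 1] grayscale image.

    A constant (for example all-black) image short-circuits to empty outputs
    with zero-length metrics rather than erroring: there is nothing to
    threshold, hence nothing to segment.
    """
    cfg = config if config is not None else PipelineConfig()
    cfg.validate()
    gray = np.asarray(img, dtype=np.float64)
    roi = cfg.roi()
    if roi is not None:
        gray = image_io.crop_roi(gray, roi)

    sp = cfg.start_params()
    gp = cfg.growth_params()

    eff_thr: float | None
    bin_thr: float | None
    try:
        eff_thr = (
            binarization.otsu_threshold(gray, cfg.binarize_n_bins)
            if sp.effective_intensity is None
            else sp.effective_intensity
        )
    except DegenerateImageError:
        eff_thr = None

    if eff_thr is None and cfg.binarize_manual_threshold is None:
        empty = np.zeros(gray.shape, dtype=bool)
        graph = skeleton.build_graph(empty)
        return SegmentationResult(
            gray=gray,
            network=network.PixelSet.empty(gray.shape),
            binary=empty,
            skeleton_raw=empty.copy(),
            graph_raw=graph,
            graph_filtered=graph,
            mask_final=empty.copy(),
            metrics=quantify.measure(empty, empty),
            component_table=skeleton.component_table(graph, cfg.filter_params()),
            effective_threshold=None,
            binarize_threshold=None,
        )

    if cfg.binarize_manual_threshold is not None:
        bin_thr = cfg.binarize_manual_threshold
        if eff_thr is None:
            eff_thr = bin_thr
    elif sp.effective_intensity is None:
        bin_thr = eff_thr
    else:
        try:
            bin_thr = binarization.otsu_threshold(gray, cfg.binarize_n_bins)
        except DegenerateImageError:
            bin_thr = eff_thr  # constant image: reuse the explicit threshold

    net = network.extract_network(gray, sp, gp, threshold=eff_thr)
    binary = binarization.binarize_network(gray, net, bin_thr)
    if cfg.binarize_fill_holes_max_area > 0:
        # Morphological cleanup: speckle dropouts punch pin-holes into the
        # binarized vessels and blobs; thinning would turn them into spurious
        # tiny rings. Filling them keeps the skeleton a tree where it should be.
        binary = remove_small_holes(binary, max_size=cfg.binarize_fill_holes_max_area)
    skel_raw = skeleton.skeletonize(binary)
    graph_raw = skeleton.build_graph(skel_raw)
    fparams = cfg.filter_params()
    graph_filtered = skeleton.filter_pieces(graph_raw, fparams)
    mask_final = skeleton.mask_from_graph(graph_filtered, binary)
    metrics = quantify.measure(
        graph_filtered.skeleton,
        mask_final,
        diagonal_weighted=cfg.quantify_diagonal_weighted,
        graph=graph_filtered,
    )
    table = skeleton.component_table(graph_raw, fparams)
    return SegmentationResult(
        gray=gray,
        network=net,
        binary=binary,
        skeleton_raw=skel_raw,
        graph_raw=graph_raw,
        graph_filtered=graph_filtered,
        mask_final=mask_final,
        metrics=metrics,
        component_table=table,
        effective_threshold=eff_thr,
        binarize_threshold=bin_thr,
    )


def segment_file(path, config: PipelineConfig | None = None) -> SegmentationResult:
    """Read an image file, normalize it, and run :func:`segment`."""
    cfg = config if config is not None else PipelineConfig()
    gray = image_io.load_gray(path, roi=None)  # ROI applied inside segment()
    return segment(gray, cfg)
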