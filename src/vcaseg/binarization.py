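"""Otsu automatic thresholding and network-restricted binarization.

The threshold is computed from the full ROI histogram and then intersected
with the grown vascular network: computing it on network pixels alone would
couple the threshold to the growth parameters, whereas the global histogram
keeps the two stages independent.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateImageError, ShapeError
from .network import PixelSet


def otsu_threshold(img: np.ndarray, n_bins: int = 256) -> float:
    """Threshold maximizing between-class variance of the intensity histogram.

    The [0, 1] range is split into ``n_bins`` equal bins; every interior bin
    edge is a candidate threshold, foreground is ``intensity >= threshold``,
    and the candidate maximizing ``w0 * w1 * (mu0 - mu1)**2`` wins. Ties go
    to the lowest qualifying threshold.

    Raises
    ------
    DegenerateImageError
        If all pixels fall into one histogram bin (constant image); callers
        may then substitute a manual threshold.
    """
    a = np.asarray(img, dtype=np.float64).ravel()
    if a.size == 0:
        raise ShapeError("cannot threshold an empty image")
    if not np.all(np.isfinite(a)) or a.min() < 0.0 or a.max() > 1.0:
        raise ShapeError("intensities must be finite and in [0, 1]")

    hist, edges = np.histogram(a, bins=n_bins, range=(0.0, 1.0))
    if np.count_nonzero(hist) < 2:
        raise DegenerateImageError("histogram has a single occupied bin; supply a manual threshold")

    centers = 0.5 * (edges[:-1] + edges[1:])
    p = hist.astype(np.float64) / hist.sum()

    # Candidate k splits bins [0, k) vs [k, n_bins); threshold is edges[k].
    w0 = np.cumsum(p)[:-1]                      # weight of class below edges[k]
    w1 = 1.0 - w0
    cum_mu = np.cumsum(p * centers)[:-1]
    total_mu = float(np.sum(p * centers))
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mu / w0
        mu1 = (total_mu - cum_mu) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between = np.where((w0 > 0) & (w1 > 0), var_between, -np.inf)

    k = int(np.argmax(var_between)) + 1         # argmax returns the first (lowest) maximizer
    return float(edges[k])


def binarize_network(img: np.ndarray, network: PixelSet, threshold: float) -> np.ndarray:
    """Boolean mask: pixel in the grown network AND intensity >= threshold."""
    a = np.asarray(img, dtype=np.float64)
    if a.shape != network.shape:
        raise ShapeError(f"image shape {a.shape} != network shape {network.shape}")
    return network.to_mask() & (a >= threshold)
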