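"""Synthetic en-face angiograms with exact ground truth.

Emulates the phenomenology of OCTA en-face images: bright branching vessel
trees of varying caliber on a darker background, multiplicative speckle
noise, elongated "tail" smears leaking downward beneath vessels, and
isolated bright noise clusters well away from any vessel. Every render comes
with its exact ground truth (vessel mask, centerline raster, pixel-count
totals), so the segmentation stages can be scored without any external data.

Vessel trees are random walks: roots sit on the image border heading inward
(plus tortuosity-scaled jitter), each step advances ``step_len`` pixels with
the heading perturbed by a Gaussian of SD ``tortuosity``, branches spawn
with probability ``branch_prob`` per step, and caliber tapers linearly from
the sampled base width toward ``width_range[0]`` at the tips. The zero-
tortuosity limit is therefore exactly axis-aligned, which pins down the
straight constant-caliber special case.

Randomness comes from ``numpy.random.default_rng`` (PCG64) seeded with an
integer, so a fixed seed reproduces the same truth bit-for-bit across runs
and platforms.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import line as _draw_line

from . import image_io
from .errors import IOFailure, ValidationError

Coord = tuple[int, int]

#: Intensity of vessel pixels in the noise-free render.
VESSEL_INTENSITY = 0.85


@dataclass(frozen=True)
class SynthParams:
    """Generator knobs; defaults are the package's standard test conditions."""

    image_size: tuple[int, int] = (256, 256)
    n_trees: int = 3
    branch_prob: float = 0.08
    width_range: tuple[float, float] = (3.0, 7.0)
    step_len: float = 3.0
    tortuosity: float = 0.25
    speckle_sigma: float = 0.15
    n_noise_clusters: int = 6
    cluster_radius_px: int = 3
    tail_artifact_strength: float = 0.4
    background_level: float = 0.15
    seed: int = 0
    max_total_length: int | None = None  # optional centerline pixel budget

    def __post_init__(self) -> None:
        rows, cols = self.image_size
        if rows < 16 or cols < 16:
            raise ValidationError("image_size: each side must be >= 16 px")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValidationError("branch_prob must lie in [0, 1]")
        wmin, wmax = self.width_range
        if wmin < 1 or wmax < wmin:
            raise ValidationError("width_range: need 1 <= min <= max")
        if self.step_len <= 0:
            raise ValidationError("step_len must be positive")
        if self.tortuosity < 0:
            raise ValidationError("tortuosity must be >= 0")
        if self.speckle_sigma < 0:
            raise ValidationError("speckle_sigma must be >= 0")
        if self.n_noise_clusters < 0 or self.cluster_radius_px < 1:
            raise ValidationError("n_noise_clusters >= 0 and cluster_radius_px >= 1 required")
        if not 0.0 <= self.tail_artifact_strength <= 1.0:
            raise ValidationError("tail_artifact_strength must lie in [0, 1]")
        if not 0.0 <= self.background_level < VESSEL_INTENSITY:
            raise ValidationError(
                f"background_level must lie in [0, {VESSEL_INTENSITY}) so vessels are brighter"
            )


@dataclass(frozen=True)
class SyntheticTruth:
    """Rendered image plus exact ground truth."""

    image: np.ndarray
    mask: np.ndarray
    centerline: np.ndarray
    total_length_px: int
    total_area_px: int
    mean_width_px: float
    noise_cluster_pixels: frozenset[Coord]
    params: SynthParams | None = None

    def cluster_mask(self) -> np.ndarray:
        m = np.zeros(self.mask.shape, dtype=bool)
        for r, c in self.noise_cluster_pixels:
            m[r, c] = True
        return m

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SyntheticTruth)
            and np.array_equal(self.image, other.image)
            and np.array_equal(self.mask, other.mask)
            and np.array_equal(self.centerline, other.centerline)
            and self.total_length_px == other.total_length_px
            and self.total_area_px == other.total_area_px
            and math.isclose(self.mean_width_px, other.mean_width_px, rel_tol=1e-12)
            and self.noise_cluster_pixels == other.noise_cluster_pixels
        )


def _disk_offsets(width: float) -> np.ndarray:
    """Offsets of a rasterized disk whose diameter matches ``width`` pixels."""
    w = max(1.0, float(width))
    radius = w / 2.0
    r = int(math.ceil(radius))
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    keep = (dr * dr + dc * dc) <= radius * radius + 1e-9
    return np.stack([dr[keep], dc[keep]], axis=1)


def _stamp(mask: np.ndarray, centers: np.ndarray, offsets: np.ndarray) -> None:
    rows, cols = mask.shape
    pts = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    ok = (pts[:, 0] >= 0) & (pts[:, 0] < rows) & (pts[:, 1] >= 0) & (pts[:, 1] < cols)
    pts = pts[ok]
    mask[pts[:, 0], pts[:, 1]] = True


def _border_root(rng: np.random.Generator, rows: int, cols: int) -> tuple[np.ndarray, float]:
    """Random border position with the inward normal as base heading."""
    side = rng.integers(0, 4)
    if side == 0:  # top edge, heading down (+row)
        return np.array([0.0, rng.uniform(2, cols - 3)]), math.pi / 2
    if side == 1:  # bottom edge, heading up
        return np.array([rows - 1.0, rng.uniform(2, cols - 3)]), -math.pi / 2
    if side == 2:  # left edge, heading right (+col)
        return np.array([rng.uniform(2, rows - 3), 0.0]), 0.0
    return np.array([rng.uniform(2, rows - 3), cols - 1.0]), math.pi


def generate(params: SynthParams) -> SyntheticTruth:
    """Render one synthetic angiogram with its exact ground truth.

    Deterministic for a fixed seed. With speckle, tails, and clusters all
    disabled the image is exactly ``background_level`` off the vessel mask
    and ``VESSEL_INTENSITY`` on it.
    """
    rng = np.random.default_rng(params.seed)
    rows, cols = params.image_size
    wmin, wmax = params.width_range

    centerline = np.zeros((rows, cols), dtype=bool)
    mask = np.zeros((rows, cols), dtype=bool)
    budget = params.max_total_length if params.max_total_length is not None else None

    # Trees are kept disjoint: a branch terminates when it approaches a
    # foreign centerline, so the ground-truth length is well defined (en-face
    # projection overlaps/crossings are deliberately not modeled). Each
    # branch carries its own trail plus the parent pixels near its origin so
    # the proximity test only fires on *foreign* vessels.
    clearance = int(math.ceil(wmax)) + 1

    def _foreign_nearby(r: int, c: int, own: set[Coord]) -> bool:
        r0, r1 = max(0, r - clearance), min(rows, r + clearance + 1)
        c0, c1 = max(0, c - clearance), min(cols, c + clearance + 1)
        win = centerline[r0:r1, c0:c1]
        if not win.any():
            return False
        wr, wc = np.nonzero(win)
        return any((int(a) + r0, int(b) + c0) not in own for a, b in zip(wr, wc))

    # (position, heading, base width, parent trail reference) per branch; the
    # parent trail is complete by the time the child runs (children are
    # processed one breadth-first pass later), and only parent pixels near the
    # spawn point are exempted so a child cannot loop back onto its parent.
    Branch = tuple[np.ndarray, float, float, set]
    queue: list[Branch] = []
    for _ in range(params.n_trees):
        pos, heading = _border_root(rng, rows, cols)
        heading += rng.normal(0.0, params.tortuosity) * 2.0
        queue.append((pos, heading, float(rng.uniform(wmin, wmax)), set()))

    exempt_radius2 = (3 * clearance) ** 2
    commit_after = 4  # steps a child must survive before its pixels are kept

    max_depth = 256  # guards runaway branching
    depth = 0
    root_attempts = 0
    while depth < max_depth:
        if not queue:
            # Under a length budget, keep seeding fresh roots until it is met.
            if budget is None or centerline.sum() >= budget or root_attempts >= 200:
                break
            root_attempts += 1
            pos, heading = _border_root(rng, rows, cols)
            heading += rng.normal(0.0, params.tortuosity) * 2.0
            queue.append((pos, heading, float(rng.uniform(wmin, wmax)), set()))
        depth += 1
        next_queue: list[Branch] = []
        budget_met = False
        for pos, heading, w0, parent_trail in queue:
            if budget_met:
                break
            sr, sc = int(round(pos[0])), int(round(pos[1]))
            trail: set[Coord] = {
                p for p in parent_trail if (p[0] - sr) ** 2 + (p[1] - sc) ** 2 <= exempt_radius2
            }
            pending: list[tuple[np.ndarray, float]] = []  # (seg, width) awaiting commit
            n_steps = int(rng.integers(20, 50))
            committed = False
            for step in range(n_steps):
                if budget is not None and centerline.sum() >= budget:
                    budget_met = True
                    break
                width = w0 + (wmin - w0) * (step / max(1, n_steps - 1))
                new = pos + params.step_len * np.array([math.sin(heading), math.cos(heading)])
                r0, c0 = int(round(pos[0])), int(round(pos[1]))
                r1, c1 = int(round(new[0])), int(round(new[1]))
                if not (0 <= r1 < rows and 0 <= c1 < cols):
                    break
                rr, cc = _draw_line(r0, c0, r1, c1)
                seg = np.stack([rr, cc], axis=1)
                seg = seg[
                    (seg[:, 0] >= 0) & (seg[:, 0] < rows) & (seg[:, 1] >= 0) & (seg[:, 1] < cols)
                ]
                if any(_foreign_nearby(int(r), int(c), trail) for r, c in seg):
                    break
                trail.update((int(r), int(c)) for r, c in seg)
                if committed:
                    centerline[seg[:, 0], seg[:, 1]] = True
                    _stamp(mask, seg, _disk_offsets(width))
                else:
                    pending.append((seg, width))
                    if step + 1 >= commit_after:
                        for pseg, pwidth in pending:
                            centerline[pseg[:, 0], pseg[:, 1]] = True
                            _stamp(mask, pseg, _disk_offsets(pwidth))
                        pending = []
                        committed = True
                pos = new
                heading += rng.normal(0.0, params.tortuosity)
                if committed and rng.uniform() < params.branch_prob and width > wmin:
                    side = 1.0 if rng.uniform() < 0.5 else -1.0
                    next_queue.append(
                        (
                            pos.copy(),
                            heading + side * rng.uniform(0.4, 1.0),
                            max(wmin, 0.7 * width),
                            trail,
                        )
                    )
            # A branch that died before the commit threshold leaves no pixels
            # (and therefore no sub-threshold stub for the filter to chew on).
        queue = [] if budget_met else next_queue
        if budget_met:
            break

    image = np.full((rows, cols), params.background_level, dtype=np.float64)
    image[mask] = VESSEL_INTENSITY

    if params.tail_artifact_strength > 0 and mask.any():
        vr, vc = np.nonzero(mask)
        tail_len = rng.integers(3, 11, size=vr.size)
        tail = np.zeros_like(image)
        for i in range(1, 11):
            sel = tail_len >= i
            rr = vr[sel] + i
            ok = rr < rows
            val = params.tail_artifact_strength * VESSEL_INTENSITY * math.exp(-i / 2.0)
            np.maximum.at(tail, (rr[ok], vc[sel][ok]), val)
        tail[mask] = 0.0
        image = np.maximum(image, params.background_level + tail)

    cluster_pixels: set[Coord] = set()
    if params.n_noise_clusters > 0:
        # Distance from every background pixel to the nearest vessel pixel.
        dist = ndimage.distance_transform_edt(~mask) if mask.any() else np.full_like(image, np.inf)
        placed = 0
        attempts = 0
        while placed < params.n_noise_clusters and attempts < 2000:
            attempts += 1
            r = int(rng.integers(params.cluster_radius_px, rows - params.cluster_radius_px))
            c = int(rng.integers(params.cluster_radius_px, cols - params.cluster_radius_px))
            if dist[r, c] < 10.0:
                continue
            radius = int(rng.integers(1, params.cluster_radius_px + 1))
            intensity = VESSEL_INTENSITY * rng.uniform(0.9, 1.0)
            offs = _disk_offsets(2 * radius + 1)
            pts = offs + np.array([r, c])
            ok = (pts[:, 0] >= 0) & (pts[:, 0] < rows) & (pts[:, 1] >= 0) & (pts[:, 1] < cols)
            pts = pts[ok]
            image[pts[:, 0], pts[:, 1]] = intensity
            cluster_pixels.update((int(a), int(b)) for a, b in pts)
            placed += 1
        if placed < params.n_noise_clusters:
            raise ValidationError(
                "could not place all noise clusters >= 10 px from vessels; "
                "reduce n_trees or n_noise_clusters"
            )

    if params.speckle_sigma > 0:
        image = image * (1.0 + params.speckle_sigma * rng.standard_normal(image.shape))
    image = np.clip(image, 0.0, 1.0)
    # Snap to the 16-bit grid so PNG round-trips reproduce the truth exactly.
    image = np.round(image * 65535.0) / 65535.0

    total_length = int(centerline.sum())
    total_area = int(mask.sum())
    mean_width = total_area / total_length if total_length else float("nan")
    return SyntheticTruth(
        image=image,
        mask=mask,
        centerline=centerline,
        total_length_px=total_length,
        total_area_px=total_area,
        mean_width_px=mean_width,
        noise_cluster_pixels=frozenset(cluster_pixels),
        params=params,
    )


def write_truth(truth: SyntheticTruth, directory: str | os.PathLike) -> Path:
    """Write the render and ground truth as PNGs plus a key=value manifest."""
    d = Path(directory)
    try:
        d.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOFailure(f"cannot create output directory {d}: {exc}") from exc
    img16 = np.round(truth.image * 65535.0).astype(np.uint16)
    import imageio.v3 as iio

    iio.imwrite(d / "image.png", img16)
    image_io.write_mask(d / "mask.png", truth.mask)
    image_io.write_mask(d / "centerline.png", truth.centerline)
    image_io.write_mask(d / "noise_clusters.png", truth.cluster_mask())
    manifest = d / "truth.txt"
    lines = [
        f"total_length_px={truth.total_length_px}",
        f"total_area_px={truth.total_area_px}",
        f"mean_width_px={truth.mean_width_px!r}",
    ]
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


def read_truth(directory: str | os.PathLike) -> SyntheticTruth:
    """Re-load a truth written by :func:`write_truth` (lossless)."""
    d = Path(directory)
    import imageio.v3 as iio

    image = np.asarray(iio.imread(d / "image.png")).astype(np.float64) / 65535.0
    mask = image_io.read_mask(d / "mask.png")
    centerline = image_io.read_mask(d / "centerline.png")
    clusters = image_io.read_mask(d / "noise_clusters.png")
    kv = {}
    for line in (d / "truth.txt").read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            kv[k.strip()] = v.strip()
    rr, cc = np.nonzero(clusters)
    return SyntheticTruth(
        image=image,
        mask=mask,
        centerline=centerline,
        total_length_px=int(kv["total_length_px"]),
        total_area_px=int(kv["total_area_px"]),
        mean_width_px=float(kv["mean_width_px"]),
        noise_cluster_pixels=frozenset(zip(rr.tolist(), cc.tolist())),
        params=None,
    )


@dataclass(frozen=True)
class StudyImage:
    subject_id: str
    day: int
    truth: SyntheticTruth


def make_study(
    n_subjects: int = 14,
    days: tuple[int, ...] = (1, 3, 5, 7),
    decline_fraction: float = 0.40,
    noise_sd: float = 0.05,
    seed: int = 0,
    base_params: SynthParams | None = None,
    base_length_range: tuple[int, int] = (700, 1100),
) -> list[StudyImage]:
    """Simulate a longitudinal study with a planted vessel-length decline.

    Each subject gets a base centerline-length budget; the budget shrinks
    linearly from 100% on the first listed day to ``1 - decline_fraction``
    on the last, with multiplicative Gaussian noise of SD ``noise_sd`` per
    rendered image. All other generator settings follow ``base_params``.
    """
    if not days or len(days) < 2:
        raise ValidationError("need at least two study days")
    if not 0.0 <= decline_fraction < 1.0:
        raise ValidationError("decline_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    base = base_params if base_params is not None else SynthParams()
    d0, d1 = days[0], days[-1]
    out: list[StudyImage] = []
    for s in range(n_subjects):
        base_len = float(rng.uniform(*base_length_range))
        for day in days:
            frac = 1.0 - decline_fraction * (day - d0) / (d1 - d0)
            target = base_len * frac * (1.0 + rng.normal(0.0, noise_sd))
            p = replace(
                base,
                seed=int(rng.integers(0, 2**31 - 1)),
                max_total_length=max(60, int(round(target))),
            )
            out.append(StudyImage(subject_id=f"S{s + 1:02d}", day=day, truth=generate(p)))
    return out
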