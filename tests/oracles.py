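"""Independent brute-force oracles.

Deliberately naive implementations (explicit loops, BFS, exhaustive search)
that never share code with the library paths they are used to check.
"""

import numpy as np

def bfs_closure(eff: np.ndarray, starts: set, d_max: float = 2.0) -> set:
    """Breadth-first closure of starts over effective pixels within d_max."""
    from collections import deque

    rows, cols = eff.shape
    r = int(np.floor(d_max))
    offsets = [
        (dr, dc)
        for dr in range(-r, r + 1)
        for dc in range(-r, r + 1)
        if (dr, dc) != (0, 0) and dr * dr + dc * dc <= d_max * d_max
    ]
    seen = set(starts)
    queue = deque(starts)
    while queue:
        pr, pc = queue.popleft()
        for dr, dc in offsets:
            q = (pr + dr, pc + dc)
            if q in seen:
                continue
            if 0 <= q[0] < rows and 0 <= q[1] < cols and eff[q]:
                seen.add(q)
                queue.append(q)
    return seen


def brute_force_starting_points(
    eff: np.ndarray, line_length: int = 7, n_directions: int = 4, pmax: float = 0.5
) -> set:
    """Per-pixel, per-line scan of the probe-line starting-point rule."""
    dirs = {
        2: [(0, 1), (1, 0)],
        4: [(0, 1), (1, 0), (1, 1), (1, -1)],
        8: [(0, 1), (1, 0), (1, 1), (1, -1), (1, 2), (2, 1), (2, -1), (1, -2)],
    }[n_directions]
    half = (line_length - 1) // 2
    rows, cols = eff.shape
    out = set()
    for r in range(rows):
        for c in range(cols):
            if not eff[r, c]:
                continue
            empty = 0
            for dr, dc in dirs:
                has_effective = False
                for j in range(-half, half + 1):
                    if j == 0:
                        continue
                    rr, cc = r + j * dr, c + j * dc
                    if 0 <= rr < rows and 0 <= cc < cols and eff[rr, cc]:
                        has_effective = True
                        break
                if not has_effective:
                    empty += 1
            if empty / len(dirs) < pmax:
                out.add((r, c))
    return out


def exhaustive_otsu(img: np.ndarray, n_bins: int = 256) -> float:
    """Search every interior bin edge for the max between-class variance."""
    vals = np.asarray(img, dtype=np.float64).ravel()
    hist, edges = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    n = hist.sum()
    best_var, best_thr = -np.inf, None
    for k in range(1, n_bins):
        n0 = hist[:k].sum()
        n1 = n - n0
        if n0 == 0 or n1 == 0:
            continue
        w0, w1 = n0 / n, n1 / n
        mu0 = (hist[:k] * centers[:k]).sum() / n0
        mu1 = (hist[k:] * centers[k:]).sum() / n1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_thr = var, edges[k]
    return float(best_thr)


def brute_force_neighbor_counts(skel: np.ndarray) -> np.ndarray:
    """Count set 8-neighbors of each skeleton pixel with explicit loops."""
    rows, cols = skel.shape
    out = np.zeros((rows, cols), dtype=int)
    for r in range(rows):
        for c in range(cols):
            if not skel[r, c]:
                continue
            n = 0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols and skel[rr, cc]:
                        n += 1
            out[r, c] = n
    return out
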