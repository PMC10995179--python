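"""Independent oracles for the geometry and clustering tests.

Everything here avoids the code paths under test: areas come from scanline
rasterization or Monte-Carlo parity sampling against the raw closed traces
(never shapely), and the agglomeration oracle is a direct O(n^3) loop over
the original distance matrix (never scipy's linkage).
"""

from __future__ import annotations

import numpy as np


def _closed(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if not np.allclose(coords[0], coords[-1]):
        coords = np.vstack([coords, coords[0]])
    return coords


def _row_crossings(coords: np.ndarray, y: float) -> np.ndarray:
    """Sorted x positions where a horizontal line crosses the closed trace."""
    x1, y1 = coords[:-1, 0], coords[:-1, 1]
    x2, y2 = coords[1:, 0], coords[1:, 1]
    m = (y1 > y) != (y2 > y)
    xs = x1[m] + (y - y1[m]) * (x2[m] - x1[m]) / (y2[m] - y1[m])
    xs.sort()
    return xs


def evenodd_area_scanline(coords: np.ndarray, n_rows: int = 4000) -> float:
    """Even-odd fill area of a closed trace by horizontal-scanline sweeping.

    Each row contributes the total length covered an odd number of times,
    integrated with the midpoint rule over ``n_rows`` strips.
    """
    coords = _closed(coords)
    y = coords[:, 1]
    y_min, y_max = y.min(), y.max()
    if y_max <= y_min:
        return 0.0
    edges = np.linspace(y_min, y_max, n_rows + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    dy = (y_max - y_min) / n_rows
    total = 0.0
    for ym in mids:
        xs = _row_crossings(coords, ym)
        if xs.size >= 2:
            total += float(np.sum(xs[1::2] - xs[: 2 * (xs.size // 2):2])) * dy
    return total


def symdiff_area_scanline(coords_a: np.ndarray, coords_b: np.ndarray,
                          n_rows: int = 4000) -> float:
    """Even-odd symmetric-difference area between two closed traces.

    Per scanline, the crossings of both traces partition the line; a segment
    belongs to the symmetric difference when the two even-odd parities
    disagree at its midpoint.
    """
    ca, cb = _closed(coords_a), _closed(coords_b)
    y_min = min(ca[:, 1].min(), cb[:, 1].min())
    y_max = max(ca[:, 1].max(), cb[:, 1].max())
    if y_max <= y_min:
        return 0.0
    edges = np.linspace(y_min, y_max, n_rows + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    dy = (y_max - y_min) / n_rows
    total = 0.0
    for ym in mids:
        xa = _row_crossings(ca, ym)
        xb = _row_crossings(cb, ym)
        bps = np.sort(np.concatenate([xa, xb]))
        if bps.size < 2:
            continue
        seg_mids = 0.5 * (bps[:-1] + bps[1:])
        pa = np.searchsorted(xa, seg_mids) % 2
        pb = np.searchsorted(xb, seg_mids) % 2
        lengths = bps[1:] - bps[:-1]
        total += float(lengths[pa != pb].sum()) * dy
    return total


def evenodd_area_montecarlo(coords: np.ndarray, n_samples: int = 400_000,
                            seed: int = 0) -> float:
    """Monte-Carlo even-odd area: parity of ray crossings at random points."""
    coords = _closed(coords)
    rng = np.random.default_rng(seed)
    x_min, y_min = coords.min(axis=0)
    x_max, y_max = coords.max(axis=0)
    px = rng.uniform(x_min, x_max, n_samples)
    py = rng.uniform(y_min, y_max, n_samples)
    x1, y1 = coords[:-1, 0], coords[:-1, 1]
    x2, y2 = coords[1:, 0], coords[1:, 1]
    inside = np.zeros(n_samples, dtype=int)
    for chunk in range(0, n_samples, 50_000):
        sl = slice(chunk, chunk + 50_000)
        qx, qy = px[sl][:, None], py[sl][:, None]
        m = (y1 > qy) != (y2 > qy)
        with np.errstate(divide="ignore", invalid="ignore"):
            xi = x1 + (qy - y1) * (x2 - x1) / (y2 - y1)
        inside[sl] = np.sum(m & (qx < xi), axis=1) % 2
    return float(inside.mean()) * (x_max - x_min) * (y_max - y_min)


def loop_coords(v) -> np.ndarray:
    """Raw closed (potential, current) trace of a voltammogram."""
    return _closed(np.column_stack([v.potential, v.current]))


# ---------------------------------------------------------------------------
# Naive agglomeration
# ---------------------------------------------------------------------------

def naive_linkage(dist: np.ndarray, method: str) -> np.ndarray:
    """O(n^3) agglomerative merge history, scipy linkage-matrix layout.

    Cluster-to-cluster distances are recomputed from the original matrix at
    every step (complete = max, single = min, average = mean over all member
    pairs); ties break on the smallest pair of node ids.
    """
    n = dist.shape[0]
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    reducers = {"complete": np.max, "single": np.min, "average": np.mean}
    reduce = reducers[method]
    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        ids = sorted(members)
        best = None
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                d = float(reduce(dist[np.ix_(members[a], members[b])]))
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        Z[step] = [a, b, d, len(members[a]) + len(members[b])]
        members[next_id] = members.pop(a) + members.pop(b)
        next_id += 1
    return Z
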