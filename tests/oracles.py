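"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most literal method available
(naive O(n²) scans, direct per-pixel formula evaluation) and stay
independent of the package's implementation paths.
"""

from __future__ import annotations

import numpy as np


def dbscan_oracle(xy: np.ndarray, eps: float, min_size: int) -> np.ndarray:
    """Textbook sequential DBSCAN with naive O(n²) neighbour search.

    Points are processed in index order with breadth-first cluster
    expansion (the classical algorithm); a core point has >= min_size
    neighbours within eps including itself.  Returns labels with -1 for
    noise.
    """
    n = len(xy)
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    neighbours = [np.flatnonzero(d2[i] <= eps**2) for i in range(n)]
    core = np.array([len(nb) >= min_size for nb in neighbours])
    labels = np.full(n, -2)  # -2 = unvisited
    cluster = -1
    for i in range(n):
        if labels[i] != -2:
            continue
        if not core[i]:
            labels[i] = -1
            continue
        cluster += 1
        labels[i] = cluster
        queue = list(neighbours[i])
        while queue:
            j = queue.pop(0)
            if labels[j] == -1:
                labels[j] = cluster  # border point reached by this core
            if labels[j] != -2:
                continue
            labels[j] = cluster
            if core[j]:
                queue.extend(neighbours[j])
    labels[labels == -2] = -1
    return labels


def elbow_oracle(values: np.ndarray) -> tuple[int, float]:
    """Single-pass elbow by explicit point-to-chord perpendicular distance
    (no iteration, no mode): the curve is (rank, value)."""
    values = np.sort(np.asarray(values, dtype=float))
    n = len(values)
    x0, y0 = 0.0, values[0]
    x1, y1 = float(n - 1), values[-1]
    best_i, best_d = 0, -1.0
    chord_len = np.hypot(x1 - x0, y1 - y0)
    for i in range(n):
        # area of the parallelogram / base = height
        d = abs((x1 - x0) * (y0 - values[i]) - (y1 - y0) * (x0 - i)) / chord_len
        if d > best_d:
            best_i, best_d = i, d
    return best_i, best_d


def box_count_oracle(mask: np.ndarray, size: int) -> int:
    """Count occupied boxes by explicit iteration over the box grid."""
    h, w = mask.shape
    count = 0
    for r0 in range(0, h, size):
        for c0 in range(0, w, size):
            if mask[r0:r0 + size, c0:c0 + size].any():
                count += 1
    return count


def partition_of(labels: np.ndarray) -> tuple[frozenset, frozenset]:
    """(noise set, set of clusters-as-frozensets) — label-permutation
    invariant representation of a clustering."""
    noise = frozenset(np.flatnonzero(labels == -1).tolist())
    clusters = frozenset(
        frozenset(np.flatnonzero(labels == k).tolist())
        for k in set(labels.tolist()) - {-1}
    )
    return noise, clusters
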