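"""Neighbor searches with optional periodic boundaries.

Fully periodic orthorhombic boxes go through ``scipy.spatial.cKDTree``
with its ``boxsize`` support; open boundaries use a plain tree; mixed
periodicity falls back to brute-force minimum-image (adequate for the
small systems that use it).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def displacements(points: np.ndarray, ref: np.ndarray, box: np.ndarray,
                  periodic: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vectors from ``ref`` to each row of ``points``."""
    d = np.asarray(points, dtype=float) - np.asarray(ref, dtype=float)
    for ax in np.nonzero(periodic)[0]:
        d[..., ax] -= box[ax] * np.round(d[..., ax] / box[ax])
    return d


def pairwise_distance_matrix(points: np.ndarray, box: np.ndarray,
                             periodic: np.ndarray) -> np.ndarray:
    """(N, N) minimum-image distance matrix (brute force)."""
    diff = points[:, None, :] - points[None, :, :]
    for ax in np.nonzero(periodic)[0]:
        diff[..., ax] -= box[ax] * np.round(diff[..., ax] / box[ax])
    return np.sqrt((diff ** 2).sum(axis=-1))


def neighbor_lists(points: np.ndarray, cutoff: float, box: np.ndarray,
                   periodic: np.ndarray) -> list[np.ndarray]:
    """Per-point index arrays of neighbors within ``cutoff`` (self excluded)."""
    points = np.asarray(points, dtype=float)
    periodic = np.asarray(periodic, dtype=bool)
    n = len(points)
    if periodic.all():
        tree = cKDTree(points % box, boxsize=box)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
    elif not periodic.any():
        tree = cKDTree(points)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
    else:
        dm = pairwise_distance_matrix(points, box, periodic)
        iu = np.triu_indices(n, k=1)
        sel = dm[iu] <= cutoff
        pairs = np.column_stack([iu[0][sel], iu[1][sel]])
    lists: list[list[int]] = [[] for _ in range(n)]
    for i, j in pairs:
        lists[i].append(j)
        lists[j].append(i)
    return [np.asarray(l, dtype=int) for l in lists]
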