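"""Shared fixtures and independent oracle implementations.

The oracles deliberately avoid the package's MST-based code path: the
barcode oracle sweeps *all* edges with a fresh union-find, and the
single-linkage oracles compute minimax path distances either by
Floyd-Warshall dynamic programming or by enumerating every simple path.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pytest

from topoconn import DistanceMatrix

# indefinite-latent-correlation repair warnings flood replicate studies
logging.getLogger("topoconn.synthetic").setLevel(logging.ERROR)


@pytest.fixture
def four_node_dm() -> DistanceMatrix:
    """The worked 4-node example: a distance matrix with known MST/SLM."""
    d = np.array(
        [
            [0.0, 0.1, 0.5, 0.9],
            [0.1, 0.0, 0.3, 0.7],
            [0.5, 0.3, 0.0, 0.4],
            [0.9, 0.7, 0.4, 0.0],
        ]
    )
    return DistanceMatrix(values=d, roi_labels=("A", "B", "C", "D"))


def random_distance_matrix(
    rng: np.random.Generator, p: int, ties: bool = False
) -> DistanceMatrix:
    """Random symmetric zero-diagonal matrix with entries in (0, 1)."""
    if ties:
        vals = rng.choice([0.2, 0.4, 0.6, 0.8], size=(p, p))
    else:
        vals = rng.uniform(0.05, 0.95, size=(p, p))
    d = np.triu(vals, k=1)
    d = d + d.T
    return DistanceMatrix(
        values=d, roi_labels=tuple(f"N{i}" for i in range(p))
    )


# ---------------------------------------------------------------------------
# oracles


def barcode_by_edge_sweep(dm: DistanceMatrix) -> list[tuple[float, int]]:
    """Merge events from a union-find sweep over ALL edges sorted by weight."""
    p = dm.n_rois
    parent = list(range(p))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    edges = sorted(
        (dm.values[i, j], i, j)
        for i in range(p)
        for j in range(i + 1, p)
    )
    events = []
    n = p
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            n -= 1
            events.append((float(w), n))
    return events


def minimax_floyd_warshall(dm: DistanceMatrix) -> np.ndarray:
    """All-pairs minimax path distance by dynamic programming over nodes."""
    m = dm.values.copy()
    p = m.shape[0]
    for k in range(p):
        m = np.minimum(m, np.maximum(m[:, k][:, None], m[k, :][None, :]))
    np.fill_diagonal(m, 0.0)
    return m


def minimax_exhaustive_paths(dm: DistanceMatrix) -> np.ndarray:
    """All-pairs minimax distance by enumerating every simple path."""
    p = dm.n_rois
    out = np.zeros((p, p))
    nodes = set(range(p))
    for i in range(p):
        for j in range(i + 1, p):
            best = np.inf
            others = sorted(nodes - {i, j})
            for k in range(len(others) + 1):
                for mid in itertools.permutations(others, k):
                    path = (i, *mid, j)
                    w = max(
                        dm.values[a, b] for a, b in zip(path, path[1:])
                    )
                    best = min(best, w)
            out[i, j] = out[j, i] = best
    return out


def all_spanning_trees_min_weight(dm: DistanceMatrix) -> float:
    """Minimum spanning-tree weight by enumerating all edge subsets."""
    p = dm.n_rois
    edges = [
        (i, j, dm.values[i, j]) for i in range(p) for j in range(i + 1, p)
    ]
    best = np.inf
    for subset in itertools.combinations(edges, p - 1):
        parent = list(range(p))

        def find(i: int) -> int:
            while parent[i] != i:
                i = parent[i]
            return i

        ok = True
        for i, j, _ in subset:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            best = min(best, sum(w for _, _, w in subset))
    return float(best)


def is_ultrametric(m: np.ndarray, atol: float = 1e-12) -> bool:
    """Check d(i,j) <= max(d(i,k), d(k,j)) for every triple."""
    a = np.maximum(m[:, None, :], m.T[None, :, :])  # a[i,j,k]=max(m[i,k],m[k,j])
    return bool(np.all(m <= a.min(axis=2) + atol))
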