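"""Graph filtration of a correlation-distance network.

Thresholding the distance matrix at every value epsilon yields a nested
sequence of binary graphs (the filtration).  The zeroth Betti number --
the number of connected components N(epsilon) -- is summarised by:

* the **barcode**: the merge events (epsilon, number of components) at
  which components fuse, which happen exactly at the minimum-spanning-tree
  edge weights;
* the **single-linkage dendrogram**: the hierarchical clustering whose
  merge heights are those same events;
* the **single-linkage matrix** (SLM): the ultrametric whose entry
  (i, j) -- the single-linkage distance, SLD -- is the smallest epsilon at
  which i and j fall into one component, equal to the maximum edge weight
  on the MST path between them (the minimax path distance);
* the **barcode slope**: the least-squares slope of N(epsilon) against
  epsilon inside a component-count window, a global-connectivity
  statistic (more negative = faster coupling of the whole network).

Everything is built on one Kruskal sweep with deterministic tie-breaking
(edges ordered by weight, then lexicographically by (i, j)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import DistanceMatrix

__all__ = [
    "Barcode",
    "Dendrogram",
    "SingleLinkageMatrix",
    "BarcodeSlope",
    "minimum_spanning_tree",
    "barcode",
    "single_linkage",
    "barcode_slope",
]


# ---------------------------------------------------------------------------
# result types


@dataclass(frozen=True)
class Barcode:
    """Beta-0 barcode: component-count step function of the filtration.

    ``merge_events`` lists, in non-decreasing epsilon order, each filtration
    value at which two components fuse together with the component count
    immediately after that merge.  For p nodes with all distances finite
    there are exactly p - 1 events, the counts stepping from p - 1 down
    to 1.
    """

    n_nodes: int
    merge_events: tuple[tuple[float, int], ...]

    def n_components(self, epsilon: float) -> int:
        """N(epsilon): components of the graph thresholded at ``epsilon``."""
        n = self.n_nodes
        for eps, after in self.merge_events:
            if eps <= epsilon:
                n = after
            else:
                break
        return n

    @property
    def epsilons(self) -> np.ndarray:
        return np.array([e for e, _ in self.merge_events])

    @property
    def component_counts(self) -> np.ndarray:
        return np.array([c for _, c in self.merge_events])


@dataclass(frozen=True)
class Dendrogram:
    """Single-linkage dendrogram as an ordered merge list.

    ``merges`` holds (cluster_a, cluster_b, height) triples in scipy
    linkage convention: leaves are clusters 0..p-1 and the k-th merge
    creates cluster p + k.  Heights are non-decreasing and reproduce the
    barcode's merge epsilons.
    """

    leaf_labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def to_linkage(self) -> np.ndarray:
        """Scipy-compatible (p-1, 4) linkage matrix (for plotting etc.)."""
        p = self.n_leaves
        sizes = {i: 1 for i in range(p)}
        z = np.zeros((p - 1, 4))
        for k, (a, b, h) in enumerate(self.merges):
            size = sizes[a] + sizes[b]
            sizes[p + k] = size
            z[k] = (a, b, h, size)
        return z

    def to_newick(self) -> str:
        """Newick string with merge heights encoded as branch lengths.

        Each node's branch length is the height difference between its
        parent merge and its own merge (leaves sit at height 0).
        """
        p = self.n_leaves
        height = {i: 0.0 for i in range(p)}
        node: dict[int, str] = {}

        def render(i: int, parent_h: float) -> str:
            return f"{node[i]}:{parent_h - height[i]:.10g}"

        for k, (a, b, h) in enumerate(self.merges):
            for c in (a, b):
                if c < p:
                    node[c] = self.leaf_labels[c]
            node[p + k] = f"({render(a, h)},{render(b, h)})"
            height[p + k] = h
        root = p + len(self.merges) - 1
        return node[root] + ";"


@dataclass(frozen=True)
class SingleLinkageMatrix:
    """Ultrametric matrix of single-linkage distances (SLDs).

    Entry (i, j) is the filtration value at which nodes i and j first
    share a connected component; it never exceeds the input distance and
    satisfies the ultrametric inequality
    ``SLM(i,j) <= max(SLM(i,k), SLM(k,j))`` for every k.
    """

    values: np.ndarray
    roi_labels: tuple[str, ...]

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    def edge_value(self, i: int, j: int) -> float:
        return float(self.values[i, j])


@dataclass(frozen=True)
class BarcodeSlope:
    """Least-squares slope of component count on filtration value.

    ``slope`` has units of components per unit filtration value and is
    negative for any non-degenerate barcode; ``n_range`` is the closed
    component-count window restricting which merge events enter the fit.
    """

    slope: float
    intercept: float
    n_range: tuple[int, int]
    n_points_used: int


# ---------------------------------------------------------------------------
# union-find


class _UnionFind:
    __slots__ = ("parent", "rank")

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        if self.rank[ri] < self.rank[rj]:
            ri, rj = rj, ri
        self.parent[rj] = ri
        if self.rank[ri] == self.rank[rj]:
            self.rank[ri] += 1
        return True


def _sorted_edges(dist: DistanceMatrix) -> list[tuple[float, int, int]]:
    d = dist.values
    p = d.shape[0]
    iu, ju = np.triu_indices(p, k=1)
    order = np.lexsort((ju, iu, d[iu, ju]))
    return [(float(d[iu[k], ju[k]]), int(iu[k]), int(ju[k])) for k in order]


# ---------------------------------------------------------------------------
# operations


def minimum_spanning_tree(dist: DistanceMatrix) -> list[tuple[int, int, float]]:
    """Kruskal MST of the complete distance graph.

    Returns the p - 1 edges ``(i, j, weight)`` with i < j, in the order
    Kruskal accepts them: by weight, ties broken lexicographically by
    (i, j), which makes the result deterministic.
    """
    p = dist.n_rois
    uf = _UnionFind(p)
    edges: list[tuple[int, int, float]] = []
    for w, i, j in _sorted_edges(dist):
        if uf.union(i, j):
            edges.append((i, j, w))
            if len(edges) == p - 1:
                break
    return edges


def barcode(dist: DistanceMatrix) -> Barcode:
    """Beta-0 barcode of the graph filtration.

    The merge events are exactly the MST edge weights in non-decreasing
    order; after the k-th event the thresholded graph has p - k connected
    components.
    """
    p = dist.n_rois
    mst = minimum_spanning_tree(dist)
    events = tuple(
        (w, p - 1 - k) for k, (_, _, w) in enumerate(mst)
    )
    return Barcode(n_nodes=p, merge_events=events)


def single_linkage(dist: DistanceMatrix) -> tuple[Dendrogram, SingleLinkageMatrix]:
    """Single-linkage dendrogram and single-linkage matrix (SLM).

    Both are read off one Kruskal sweep: when components A and B fuse at
    edge weight w, every cross pair (a in A, b in B) receives SLD w, and
    the dendrogram records the merge at height w.  The SLD equals the
    minimax path distance (max edge weight on the MST path) between the
    two nodes.
    """
    p = dist.n_rois
    slm = np.zeros((p, p))
    uf = _UnionFind(p)
    members: dict[int, list[int]] = {i: [i] for i in range(p)}
    cluster_id: dict[int, int] = {i: i for i in range(p)}
    merges: list[tuple[int, int, float]] = []
    next_id = p
    for w, i, j in _sorted_edges(dist):
        ri, rj = uf.find(i), uf.find(j)
        if ri == rj:
            continue
        a, b = members[ri], members[rj]
        slm[np.ix_(a, b)] = w
        slm[np.ix_(b, a)] = w
        merges.append((cluster_id[ri], cluster_id[rj], w))
        uf.union(i, j)
        root = uf.find(i)
        members[root] = a + b
        other = rj if root == ri else ri
        if other != root:
            del members[other]
        cluster_id[root] = next_id
        next_id += 1
        if len(merges) == p - 1:
            break
    dendro = Dendrogram(leaf_labels=dist.roi_labels, merges=tuple(merges))
    return dendro, SingleLinkageMatrix(values=slm, roi_labels=dist.roi_labels)


def barcode_slope(
    bc: Barcode,
    n_range: tuple[int, int] = (11, 66),
    grid: int | None = None,
) -> BarcodeSlope:
    """OLS slope of component count (response) on epsilon (predictor).

    Only merge events whose component count lies in the closed window
    ``n_range`` enter the regression.  The default window 11-66 targets
    the near-linear mid-section of a 76-node barcode; for other network
    sizes pass a window that sits inside (1, p - 1).

    Parameters
    ----------
    bc : Barcode
    n_range : (int, int)
        Closed component-count window (low, high).
    grid : int, optional
        If given, regress on ``grid`` evenly spaced epsilon samples of the
        step function N(epsilon) over the in-window epsilon span instead
        of on the merge events themselves.

    Raises
    ------
    ValueError
        If fewer than 2 events fall in the window, or the in-window
        epsilons have zero variance (slope undefined).
    """
    low, high = n_range
    if not low < high:
        raise ValueError(f"window low must be < high, got {n_range}")
    eps = bc.epsilons
    counts = bc.component_counts
    mask = (counts >= low) & (counts <= high)
    if mask.sum() < 2:
        raise ValueError(
            f"need at least 2 merge events with component count in "
            f"[{low}, {high}]; found {int(mask.sum())}"
        )
    x, y = eps[mask], counts[mask].astype(float)
    if grid is not None:
        xs = np.linspace(x.min(), x.max(), grid)
        x, y = xs, np.array([bc.n_components(e) for e in xs], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("in-window epsilons have zero variance; slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    return BarcodeSlope(
        slope=float(slope),
        intercept=float(intercept),
        n_range=(low, high),
        n_points_used=int(len(x)),
    )
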