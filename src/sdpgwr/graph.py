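"""Areal graphs, distance matrices, and geographically weighted regression kernels.

Areal (lattice) data come as polygons with centroids and a contiguity
structure.  Two distance metrics between areas are supported: the graph
distance (number of edges on a shortest path through the contiguity graph)
and the great-circle distance between centroids.  Either feeds the GWR
weight rule

    w(d) = 1            if d <= threshold,
    w(d) = exp(-d / b)  otherwise,

where ``b`` is the bandwidth controlling decay.  Pairs of areas in different
connected components are "infinitely" far apart and receive weight 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel marking an unreachable pair in a graph distance matrix.
UNREACHABLE = np.inf


@dataclass
class AreaGraph:
    """Contiguity graph over areal units.

    Parameters
    ----------
    area_ids
        Ordered unique identifiers, one per area.
    centroids
        ``(n, 2)`` array of per-area coordinates. Planar ``(x, y)`` or
        spherical ``(lon, lat)`` depending on the distance metric used.
    edges
        Normalized set of unordered index pairs ``(i, j)`` with ``i < j``.
    """

    area_ids: list
    centroids: np.ndarray
    edges: set = field(default_factory=set)

    @property
    def n(self) -> int:
        return len(self.area_ids)

    def index_of(self, area_id) -> int:
        return self._index[area_id]

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape != (len(self.area_ids), 2):
            raise ValueError(
                f"centroids must be (n, 2); got {self.centroids.shape} "
                f"for {len(self.area_ids)} areas"
            )
        self._index = {a: i for i, a in enumerate(self.area_ids)}
        if len(self._index) != len(self.area_ids):
            raise ValueError("duplicate area id")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx())


def build_area_graph(area_table, edge_list) -> AreaGraph:
    """Assemble a normalized :class:`AreaGraph`.

    ``area_table`` is a pandas DataFrame with columns ``area_id``, ``lon``,
    ``lat`` (coordinate columns may equally hold planar x/y).  ``edge_list``
    is an iterable of id pairs.  Self-edges are dropped with a warning and
    duplicate edges collapse; an edge naming an unknown id is an error.
    """
    ids = list(area_table["area_id"])
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate area id in area table")
    centroids = np.column_stack(
        [np.asarray(area_table["lon"], float), np.asarray(area_table["lat"], float)]
    )
    graph = AreaGraph(ids, centroids)
    edges = set()
    for a, b in edge_list:
        if a not in graph._index:
            raise ValueError(f"edge references unknown area id {a!r}")
        if b not in graph._index:
            raise ValueError(f"edge references unknown area id {b!r}")
        i, j = graph.index_of(a), graph.index_of(b)
        if i == j:
            logger.warning("dropping self-edge on area %r", a)
            continue
        edges.add((min(i, j), max(i, j)))
    graph.edges = edges
    return graph


def graph_distance_matrix(graph: AreaGraph) -> np.ndarray:
    """All-pairs shortest-path edge counts; unreachable pairs get ``inf``."""
    g = graph.to_networkx()
    n = graph.n
    dist = np.full((n, n), UNREACHABLE)
    for i, lengths in nx.all_pairs_shortest_path_length(g):
        for j, d in lengths.items():
            dist[i, j] = d
    np.fill_diagonal(dist, 0.0)
    return dist


def great_circle_distance_matrix(centroids: np.ndarray, radius: float = 6371.0) -> np.ndarray:
    """Haversine distance matrix for ``(lon, lat)`` centroids in degrees."""
    centroids = np.asarray(centroids, dtype=float)
    lat = centroids[:, 1]
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    lon_r = np.radians(centroids[:, 0])
    lat_r = np.radians(lat)
    dlat = lat_r[:, None] - lat_r[None, :]
    dlon = lon_r[:, None] - lon_r[None, :]
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat_r)[:, None] * np.cos(lat_r)[None, :] * np.sin(dlon / 2.0) ** 2
    h = np.clip(h, 0.0, 1.0)
    dist = 2.0 * radius * np.arcsin(np.sqrt(h))
    np.fill_diagonal(dist, 0.0)
    return dist


def euclidean_distance_matrix(centroids: np.ndarray) -> np.ndarray:
    centroids = np.asarray(centroids, dtype=float)
    diff = centroids[:, None, :] - centroids[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


def gwr_weights(distances: np.ndarray, b: float, threshold: float = 1.0) -> np.ndarray:
    """GWR weight matrix: 1 within ``threshold``, negative-exponential decay beyond.

    Row ``s`` holds the diagonal of the local weight matrix W(s).
    Unreachable pairs (``inf`` distance) map to weight 0, the limit of
    ``exp(-d/b)`` as d grows; ``b`` must be positive.

    For graph distances the default ``threshold=1`` gives an area and its
    contiguous neighbours full weight.  With metric distances, pass
    ``threshold=0`` so only the area itself is pinned at 1.
    """
    if not b > 0:
        raise ValueError(f"bandwidth must be positive, got {b}")
    distances = np.asarray(distances, dtype=float)
    with np.errstate(over="ignore"):
        w = np.where(distances <= threshold, 1.0, np.exp(-distances / b))
    w[~np.isfinite(distances)] = 0.0
    return w
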