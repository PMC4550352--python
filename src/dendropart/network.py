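"""Dendritic stream-network data model and network distance matrices.

A stream network is a rooted tree (or forest): nodes carry planar
coordinates and elevations, segments carry lengths and flow direction
(upstream node -> downstream node).  Sites are the subset of nodes at
which communities and environments were observed.  All distances used
downstream of this module (overland, watercourse, altitudinal) are
computed here; glaciality distances live in :mod:`dendropart.glaciality`.

Coordinates are planar projected metres; at the ~10 km extent of an
alpine catchment, geodesic corrections are negligible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "StreamNetwork",
    "DistanceMatrix",
    "NetworkStructureError",
    "build_network",
    "overland_distance_matrix",
    "watercourse_distance_matrix",
    "watercourse_altitudinal_matrix",
    "overland_altitudinal_matrix",
    "downstream_connectivity",
]

#: distance-matrix kinds that the pipeline may construct.  There is
#: deliberately no "overland_gla": glaciality does not vary through the air.
DIST_TYPES = frozenset(
    {
        "overland_geo",
        "watercourse_geo",
        "overland_alt",
        "watercourse_alt",
        "watercourse_gla",
        "downstream_geo",
        "downstream_alt",
        "downstream_gla",
    }
)


class NetworkStructureError(ValueError):
    """Raised when node/segment tables violate the dendritic-tree invariants."""


@dataclass
class DistanceMatrix:
    """Symmetric site-by-site distance matrix of one kind.

    Parameters
    ----------
    values : (n, n) ndarray
        Nonnegative, symmetric, zero diagonal.
    labels : list
        Site identifiers, in row/column order.
    dist_type : str
        One of the kinds in :data:`DIST_TYPES`.
    """

    values: np.ndarray
    labels: list
    dist_type: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dist_type not in DIST_TYPES:
            raise ValueError(f"unknown dist_type {self.dist_type!r}")
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values shape does not match labels")
        finite = np.isfinite(self.values)
        if np.any(self.values[finite] < 0):
            raise ValueError("negative distances")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("nonzero diagonal")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="site_id")

    @classmethod
    def from_csv(cls, path, dist_type: str) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), list(df.index), dist_type)


@dataclass
class StreamNetwork:
    """Rooted dendritic network of nodes and flow-directed segments.

    ``nodes`` requires columns ``node_id, x, y, elevation, is_site`` and
    optionally ``site_class`` (``first_order`` / ``mainstem`` / ``none``).
    ``segments`` requires ``segment_id, up_node, down_node, length`` and
    optionally ``glaciality``.
    """

    nodes: pd.DataFrame
    segments: pd.DataFrame
    outlet: object = None
    graph: nx.DiGraph = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.graph is None:
            g = nx.DiGraph()
            for row in self.nodes.itertuples(index=False):
                g.add_node(
                    row.node_id,
                    x=float(row.x),
                    y=float(row.y),
                    elevation=float(row.elevation),
                    is_site=bool(row.is_site),
                )
            for row in self.segments.itertuples(index=False):
                g.add_edge(
                    row.up_node,
                    row.down_node,
                    segment_id=row.segment_id,
                    length=float(row.length),
                    glaciality=float(getattr(row, "glaciality", np.nan)),
                )
            self.graph = g

    # -- basic views ---------------------------------------------------
    @property
    def site_ids(self) -> list:
        return list(self.nodes.loc[self.nodes["is_site"].astype(bool), "node_id"])

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def node_attr(self, attr: str) -> dict:
        return dict(zip(self.nodes["node_id"], self.nodes[attr]))

    def undirected(self) -> nx.Graph:
        return self.graph.to_undirected(as_view=True)

    def headwaters(self) -> list:
        """Nodes with no upstream segment (sources of the flow graph)."""
        return [n for n in self.graph.nodes if self.graph.in_degree(n) == 0]

    def path_nodes(self, a, b) -> list:
        """Nodes on the unique undirected tree path between a and b."""
        return nx.shortest_path(self.undirected(), a, b)

    def set_segment_glaciality(self, values: dict) -> None:
        """Attach glaciality values keyed by segment_id to segments and graph."""
        self.segments = self.segments.copy()
        self.segments["glaciality"] = self.segments["segment_id"].map(values)
        for _, _, data in self.graph.edges(data=True):
            data["glaciality"] = float(values[data["segment_id"]])


def build_network(
    node_table: pd.DataFrame,
    segment_table: pd.DataFrame,
    *,
    elevation_errors: str = "warn",
) -> StreamNetwork:
    """Validate node/segment tables and assemble a :class:`StreamNetwork`.

    Site classes are assigned from the Strahler order of the segment tree
    (order-1 sites are ``first_order``, the rest ``mainstem``) unless the
    node table supplies a ``site_class`` column with non-null overrides.

    Parameters
    ----------
    elevation_errors : {"warn", "raise", "ignore"}
        What to do when a segment runs uphill (upstream node lower than its
        downstream node).

    Raises
    ------
    NetworkStructureError
        On cycles, nodes with multiple downstream segments, orphan segments,
        or non-positive segment lengths, naming the offending element.
    """
    nodes = node_table.copy().reset_index(drop=True)
    segments = segment_table.copy().reset_index(drop=True)

    node_ids = set(nodes["node_id"])
    if len(node_ids) != len(nodes):
        raise NetworkStructureError("duplicate node ids")
    for row in segments.itertuples(index=False):
        for end in (row.up_node, row.down_node):
            if end not in node_ids:
                raise NetworkStructureError(
                    f"orphan segment {row.segment_id!r}: unknown node {end!r}"
                )
        if not row.length > 0:
            raise NetworkStructureError(
                f"segment {row.segment_id!r} has non-positive length {row.length}"
            )

    down_counts = segments.groupby("up_node").size()
    multi = down_counts[down_counts > 1]
    if len(multi):
        raise NetworkStructureError(
            f"multiple downstream segments from node(s) {list(multi.index)!r}"
        )

    g = nx.DiGraph()
    g.add_nodes_from(nodes["node_id"])
    g.add_edges_from(zip(segments["up_node"], segments["down_node"]))
    if len(g.edges) != len(segments):
        raise NetworkStructureError("duplicate segment between same node pair")
    und = g.to_undirected()
    n_comp = nx.number_connected_components(und)
    if len(segments) != len(nodes) - n_comp:
        raise NetworkStructureError("cycle detected: segment count exceeds tree bound")

    elev = dict(zip(nodes["node_id"], nodes["elevation"]))
    uphill = [
        row.segment_id
        for row in segments.itertuples(index=False)
        if elev[row.up_node] < elev[row.down_node]
    ]
    if uphill:
        msg = f"segments run uphill: {uphill!r}"
        if elevation_errors == "raise":
            raise NetworkStructureError(msg)
        if elevation_errors == "warn":
            warnings.warn(msg, stacklevel=2)

    # outlet: the terminal node of the largest component
    outlets = [n for n in g.nodes if g.out_degree(n) == 0]
    comp_size = {n: len(nx.node_connected_component(und, n)) for n in outlets}
    outlet = max(outlets, key=lambda n: (comp_size[n], str(n)))

    order = strahler_order(g)
    if "site_class" not in nodes.columns:
        nodes["site_class"] = None
    auto = nodes["node_id"].map(
        lambda n: "first_order" if order[n] <= 1 else "mainstem"
    )
    nodes["site_class"] = nodes["site_class"].where(
        nodes["site_class"].notna() & (nodes["site_class"] != ""), auto
    )
    nodes.loc[~nodes["is_site"].astype(bool), "site_class"] = "none"

    return StreamNetwork(nodes=nodes, segments=segments, outlet=outlet)


def strahler_order(g: nx.DiGraph) -> dict:
    """Strahler stream order per node on a flow-directed forest."""
    order: dict = {}
    for n in nx.topological_sort(g):
        ups = [order[u] for u in g.predecessors(n)]
        if not ups:
            order[n] = 1
        else:
            top = max(ups)
            order[n] = top + 1 if ups.count(top) >= 2 else top
    return order


def _site_positions(network: StreamNetwork) -> tuple[list, np.ndarray]:
    sites = network.nodes[network.nodes["is_site"].astype(bool)]
    xy = sites[["x", "y"]].to_numpy(dtype=float)
    if np.any(~np.isfinite(xy)):
        raise ValueError("missing site coordinates")
    return list(sites["node_id"]), xy


def overland_distance_matrix(network: StreamNetwork) -> DistanceMatrix:
    """Straight-line (Euclidean, planar) distances between all site pairs."""
    labels, xy = _site_positions(network)
    diff = xy[:, None, :] - xy[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    return DistanceMatrix(d, labels, "overland_geo")


def _pairwise_tree(network: StreamNetwork, pair_value, dist_type: str,
                   allow_missing: bool = True) -> DistanceMatrix:
    labels = network.site_ids
    und = network.undirected()
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = pair_value(und, labels[i], labels[j])
            except nx.NetworkXNoPath:
                if not allow_missing:
                    raise ValueError(
                        f"sites {labels[i]!r} and {labels[j]!r} are in "
                        "disconnected components"
                    ) from None
                d[i, j] = d[j, i] = np.nan
    return DistanceMatrix(d, labels, dist_type)


def watercourse_distance_matrix(
    network: StreamNetwork, *, allow_missing: bool = True
) -> DistanceMatrix:
    """Along-channel distances: summed segment lengths on the tree path.

    Pairs in disconnected components get NaN (or raise when
    ``allow_missing=False``).
    """
    und = network.undirected()
    labels = network.site_ids
    # single-source Dijkstra from each site; on a tree this is exact path sum
    n = len(labels)
    d = np.full((n, n), np.nan)
    idx = {s: i for i, s in enumerate(labels)}
    for i, s in enumerate(labels):
        lengths = nx.single_source_dijkstra_path_length(und, s, weight="length")
        for t, v in lengths.items():
            if t in idx:
                d[i, idx[t]] = v
    if not allow_missing and np.any(np.isnan(d)):
        bad = np.argwhere(np.isnan(d))[0]
        raise ValueError(
            f"sites {labels[bad[0]]!r} and {labels[bad[1]]!r} are disconnected"
        )
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, labels, "watercourse_geo")


def watercourse_altitudinal_matrix(
    network: StreamNetwork, *, allow_missing: bool = True
) -> DistanceMatrix:
    """Relief along the channel: max minus min node elevation on the path."""
    elev = network.node_attr("elevation")

    def relief(und, a, b):
        path = nx.shortest_path(und, a, b)
        z = [elev[p] for p in path]
        return max(z) - min(z)

    return _pairwise_tree(network, relief, "watercourse_alt", allow_missing)


def overland_altitudinal_matrix(
    network: StreamNetwork, raster, step: float | None = None
) -> DistanceMatrix:
    """Relief along the straight line between sites, sampled from a DEM.

    ``step`` defaults to the raster cell size (see
    :func:`dendropart.raster.line_relief`).
    """
    from .raster import line_relief

    labels, xy = _site_positions(network)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = line_relief(raster, xy[i], xy[j], step=step)
    return DistanceMatrix(d, labels, "overland_alt")


def downstream_connectivity(network: StreamNetwork) -> pd.DataFrame:
    """Boolean site-by-site relation: R[i, j] is True iff water flowing from
    site j passes through site i (i lies downstream of j)."""
    labels = network.site_ids
    sites = set(labels)
    n = len(labels)
    r = np.zeros((n, n), dtype=bool)
    idx = {s: i for i, s in enumerate(labels)}
    for j, s in enumerate(labels):
        for t in nx.descendants(network.graph, s):
            if t in sites:
                r[idx[t], j] = True
    return pd.DataFrame(r, index=labels, columns=labels)
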