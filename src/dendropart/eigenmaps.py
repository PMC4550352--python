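"""Spatial eigenfunctions: Moran's eigenvector maps and asymmetric
eigenvector maps on directional stream networks.

MEM here is the distance-based (PCNM) construction: truncate a symmetric
distance matrix at a neighbourhood threshold (default: the largest edge of
its minimum spanning tree, the smallest threshold keeping the graph
connected), replace beyond-threshold distances by four times the threshold,
and take the principal coordinates of the modified matrix.  Eigenvectors
with positive eigenvalues model positive spatial autocorrelation at
successively finer scales.

AEM encodes flow direction.  Every site is described by the set of edges
that water traverses from a virtual upstream origin (connected to all
headwaters) down to the site; the site-by-edge incidence matrix, with
columns weighted by an edge resistance, column-centred and decomposed by
SVD, yields orthogonal eigenfunctions of the directional process.  Because
AEM singular values are always nonnegative, axes are classified as
positively or negatively autocorrelated by Moran's I against binary
channel-neighbour weights (sites adjacent along the channel).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree

from .network import DistanceMatrix, StreamNetwork

__all__ = [
    "EigenfunctionSet",
    "mem_eigenfunctions",
    "aem_edge_weights",
    "aem_eigenfunctions",
    "morans_i",
    "positive_eigenfunction_filter",
]

#: relative threshold below which an eigenvalue / singular value is
#: treated as numerically zero
RANK_TOL = 1e-10


@dataclass
class EigenfunctionSet:
    """Orthogonal spatial basis with metadata.

    ``basis`` is n×k with unit-norm, mutually orthogonal, centred columns;
    ``eigenvalues`` are PCoA eigenvalues (MEM) or squared singular values
    (AEM), sorted decreasing; ``morans_i`` holds Moran's I of each column
    against the weight matrix recorded in ``meta``.
    """

    basis: np.ndarray
    eigenvalues: np.ndarray
    morans_i: np.ndarray
    construction: str           # "MEM" | "AEM"
    dist_type: str
    labels: list
    meta: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return 0 if self.basis.size == 0 else self.basis.shape[1]

    @property
    def is_empty(self) -> bool:
        return self.k == 0

    def select(self, cols) -> np.ndarray:
        return self.basis[:, list(cols)]

    def to_csv(self, path, meta_path=None) -> None:
        import pandas as pd

        cols = [f"{self.construction}{i + 1}" for i in range(self.k)]
        pd.DataFrame(self.basis, index=self.labels, columns=cols).to_csv(
            path, index_label="site_id"
        )
        if meta_path is not None:
            payload = {
                "construction": self.construction,
                "dist_type": self.dist_type,
                "eigenvalues": list(map(float, self.eigenvalues)),
                "morans_i": list(map(float, self.morans_i)),
                **self.meta,
            }
            with open(meta_path, "w") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Deterministic column signs: largest-|entry| component positive."""
    for k in range(vecs.shape[1]):
        j = int(np.argmax(np.abs(vecs[:, k])))
        if vecs[j, k] < 0:
            vecs[:, k] = -vecs[:, k]
    return vecs


def morans_i(v: np.ndarray, w: np.ndarray) -> float:
    """Moran's I of vector v under weight matrix w.

    I = (n / ΣW) · (v_cᵀ W v_c) / (v_cᵀ v_c) with v_c the centred vector.
    """
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    n = v.shape[0]
    vc = v - v.mean()
    denom = float(vc @ vc)
    if denom == 0:
        raise ValueError("Moran's I undefined for a constant vector")
    s = w.sum()
    if s == 0:
        raise ValueError("weight matrix sums to zero")
    return float(n / s * (vc @ w @ vc) / denom)


def mem_eigenfunctions(
    D: DistanceMatrix, truncation: float | None = None
) -> EigenfunctionSet:
    """Distance-based Moran's eigenvector maps (PCNM variant).

    Parameters
    ----------
    D : DistanceMatrix
        Symmetric distances; must not contain missing values.
    truncation : float, optional
        Neighbourhood threshold t.  Defaults to the longest edge of the
        minimum spanning tree of D.  Distances beyond t are replaced by 4t
        before principal-coordinate analysis.  Raises if the graph of
        within-threshold pairs is disconnected.

    Returns only the axes with positive eigenvalues (relative tolerance
    1e−10 of the leading eigenvalue).
    """
    d = np.asarray(D.values, dtype=float)
    if np.any(~np.isfinite(d)):
        raise ValueError("distance matrix contains missing values")
    n = d.shape[0]
    mst = minimum_spanning_tree(d).toarray()
    t_min = float(mst.max())
    t = t_min if truncation is None else float(truncation)
    adj = (d <= t) & ~np.eye(n, dtype=bool)
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp > 1:
        raise ValueError(
            f"threshold {t:g} disconnects the network "
            f"(minimum connecting threshold is {t_min:g}); increase truncation"
        )
    dstar = np.where(adj | np.eye(n, dtype=bool), d, 4.0 * t)
    # Gower double-centring of -1/2 D*^2
    a = -0.5 * dstar**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    b = (b + b.T) / 2.0
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > RANK_TOL * max(vals[0], 0.0)
    vals, vecs = vals[keep], vecs[:, keep]
    vecs = _fix_signs(vecs)
    w = adj.astype(float)
    mi = np.array([morans_i(vecs[:, k], w) for k in range(vecs.shape[1])])
    return EigenfunctionSet(
        basis=vecs,
        eigenvalues=vals,
        morans_i=mi,
        construction="MEM",
        dist_type=D.dist_type,
        labels=list(D.labels),
        meta={"truncation": t, "weights": "binary within-threshold"},
    )


def aem_edge_weights(
    distances: np.ndarray, scheme: str = "linear", alpha: float = 1.0
) -> np.ndarray:
    """Edge resistance weights w = 1 − (d / d_max)^alpha with a 1e−6 floor.

    The floor keeps the most costly edge attached (a partial barrier, not
    a disconnection).  With all distances equal, all weights are equal.
    """
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("negative edge distance")
    if scheme != "linear":
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    dmax = d.max()
    if dmax == 0:
        return np.ones_like(d)
    w = 1.0 - (d / dmax) ** alpha
    return np.maximum(w, 1e-6)


def _site_adjacency(network: StreamNetwork, labels: list) -> np.ndarray:
    """Binary channel-neighbour weights: two sites are neighbours when the
    channel path between them passes through no other listed site."""
    import networkx as nx

    und = network.undirected()
    idx = {s: i for i, s in enumerate(labels)}
    sites = set(labels)
    n = len(labels)
    w = np.zeros((n, n))
    for s in labels:
        # BFS outward from s, stopping at the first site in each direction
        seen = {s}
        frontier = [s]
        while frontier:
            nxt = []
            for node in frontier:
                for nb in und.neighbors(node):
                    if nb in seen:
                        continue
                    seen.add(nb)
                    if nb in sites:
                        w[idx[s], idx[nb]] = w[idx[nb], idx[s]] = 1.0
                    else:
                        nxt.append(nb)
            frontier = nxt
    return w


def aem_eigenfunctions(
    network: StreamNetwork,
    edge_weights: dict | None = None,
    dist_type: str = "downstream_geo",
    site_subset: list | None = None,
) -> EigenfunctionSet:
    """Asymmetric eigenvector maps from the directed stream network.

    ``edge_weights`` maps segment_id -> weight (default all 1).  A virtual
    origin upstream of every headwater contributes weight-1 edges.  The
    site-by-edge incidence matrix records, for each site, the edges on the
    directed path from the origin; columns are weighted, centred, and
    decomposed by SVD.  ``site_subset`` restricts the rows (and the
    channel-neighbour weights used for Moran's I) to the given sites.
    """
    g = network.graph
    labels = site_subset if site_subset is not None else network.site_ids
    segs = network.segments.sort_values("segment_id", kind="stable")
    edge_ids = list(segs["segment_id"])
    if edge_weights is None:
        edge_weights = {e: 1.0 for e in edge_ids}
    heads = sorted(network.headwaters(), key=str)
    all_edges = edge_ids + [("origin", h) for h in heads]
    wvec = np.array(
        [float(edge_weights[e]) for e in edge_ids] + [1.0] * len(heads)
    )

    # edges upstream of each node = edges on the directed origin->node path
    edge_pos = {e: i for i, e in enumerate(edge_ids)}
    seg_by_edge = {
        (r.up_node, r.down_node): r.segment_id for r in segs.itertuples(index=False)
    }
    import networkx as nx

    upstream_edges: dict = {}
    for node in nx.topological_sort(g):
        preds = list(g.predecessors(node))
        acc = set()
        if not preds:  # headwater: virtual origin edge
            acc.add(len(edge_ids) + heads.index(node))
        for p in preds:
            acc |= upstream_edges[p]
            acc.add(edge_pos[seg_by_edge[(p, node)]])
        upstream_edges[node] = acc

    n = len(labels)
    e_mat = np.zeros((n, len(all_edges)))
    for i, s in enumerate(labels):
        for k in upstream_edges[s]:
            e_mat[i, k] = 1.0
    nonzero = e_mat.sum(axis=0) > 0  # edges with no site downstream drop out
    e_mat, wvec = e_mat[:, nonzero], wvec[nonzero]
    ew = e_mat * wvec
    ew = ew - ew.mean(axis=0)
    u, s, _ = np.linalg.svd(ew, full_matrices=False)
    keep = s > RANK_TOL * (s[0] if s.size else 0.0)
    u, s = u[:, keep], s[keep]
    u = _fix_signs(u)

    w = _site_adjacency(network, labels)
    mi = np.array([morans_i(u[:, k], w) for k in range(u.shape[1])])
    return EigenfunctionSet(
        basis=u,
        eigenvalues=s**2,
        morans_i=mi,
        construction="AEM",
        dist_type=dist_type,
        labels=list(labels),
        meta={
            "weights": "1 - (d/dmax)^alpha with 1e-6 floor",
            "moran_expectation": -1.0 / (len(labels) - 1),
        },
    )


def positive_eigenfunction_filter(es: EigenfunctionSet) -> EigenfunctionSet:
    """Keep axes modelling positive spatial autocorrelation.

    MEM: positive eigenvalues (the construction already retains these, so
    this is idempotent).  AEM: Moran's I above its null expectation
    −1/(n−1).  An empty result is returned with ``is_empty`` set so the
    pipeline can report "no spatial structure".
    """
    n = len(es.labels)
    if es.construction == "MEM":
        keep = es.eigenvalues > 0
    else:
        keep = es.morans_i > (-1.0 / (n - 1))
    return EigenfunctionSet(
        basis=es.basis[:, keep],
        eigenvalues=es.eigenvalues[keep],
        morans_i=es.morans_i[keep],
        construction=es.construction,
        dist_type=es.dist_type,
        labels=list(es.labels),
        meta=dict(es.meta),
    )
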