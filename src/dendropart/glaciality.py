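"""Glaciality index and glaciality distances on the stream network.

The glaciality index summarises glacial influence at a site from four
harshness variables — water temperature, conductivity, 1/turbidity and
1/Pfankuch (channel-bottom stability score) — each scaled to [0, 1] and
ordinated by a *non-centred* PCA.  Axis-1 site scores, oriented so that
glacially harsh sites (uniformly low values of all four scaled variables)
score highest and shifted to be nonnegative, form the index.  Segment-level
glaciality then propagates the site index along the network, and the
glaciality distance between two sites is the range (max − min) of
glaciality encountered along the channel path connecting them.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import DistanceMatrix, StreamNetwork

__all__ = [
    "GLACIER_VARS",
    "INSTREAM_VARS",
    "RESOURCE_VARS",
    "minmax_scale",
    "noncentred_pca",
    "glaciality_index",
    "assign_segment_glaciality",
    "glaciality_distance_matrix",
]

GLACIER_VARS = ["temperature", "conductivity", "turbidity", "pfankuch"]
INSTREAM_VARS = ["width", "depth", "slope", "ph"]
RESOURCE_VARS = ["epilithic_algae", "benthic_om"]


def minmax_scale(df: pd.DataFrame) -> pd.DataFrame:
    """Scale each column to [0, 1] as (x − min) / (max − min).

    Raises ``ValueError`` naming the first constant column found.
    """
    out = {}
    for col in df.columns:
        x = df[col].to_numpy(dtype=float)
        lo, hi = np.min(x), np.max(x)
        if hi == lo:
            raise ValueError(f"column {col!r} is constant; cannot min-max scale")
        out[col] = (x - lo) / (hi - lo)
    return pd.DataFrame(out, index=df.index)


@dataclass
class NPCAResult:
    scores: np.ndarray      # n x k, U * S
    loadings: np.ndarray    # m x k, columns of V
    eigenvalues: np.ndarray  # k, = S^2 / n, decreasing


def noncentred_pca(X: np.ndarray) -> NPCAResult:
    """Non-centred principal component analysis via SVD of the raw matrix.

    Unlike ordinary PCA the column means are *not* removed, so axis 1
    captures the overall size axis of a nonnegative table.  Scores carry
    the singular values (scores = U·S); eigenvalues are S²/n.  Axis signs
    are fixed so each loading column's largest-magnitude entry is positive.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in NPCA input")
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    v = vt.T
    # deterministic sign: largest-|loading| entry positive per axis
    for k in range(v.shape[1]):
        j = int(np.argmax(np.abs(v[:, k])))
        if v[j, k] < 0:
            v[:, k] = -v[:, k]
            u[:, k] = -u[:, k]
    return NPCAResult(scores=u * s, loadings=v, eigenvalues=s**2 / X.shape[0])


def glaciality_index(env: pd.DataFrame) -> pd.Series:
    """Per-site glaciality score from the four harshness variables.

    ``env`` must contain columns ``temperature``, ``conductivity``,
    ``turbidity`` and ``pfankuch`` (all > 0 for the reciprocal variables).
    Returns a Series indexed like ``env`` with minimum 0 and the highest
    values at the most glacially influenced sites.
    """
    for col in GLACIER_VARS:
        if col not in env.columns:
            raise ValueError(f"missing glacier variable {col!r}")
    if np.any(env["turbidity"].to_numpy(dtype=float) <= 0):
        raise ValueError("turbidity must be > 0 (reciprocal is taken)")
    if np.any(env["pfankuch"].to_numpy(dtype=float) <= 0):
        raise ValueError("pfankuch must be > 0 (reciprocal is taken)")
    harsh = pd.DataFrame(
        {
            "temperature": env["temperature"].astype(float),
            "conductivity": env["conductivity"].astype(float),
            "inv_turbidity": 1.0 / env["turbidity"].astype(float),
            "inv_pfankuch": 1.0 / env["pfankuch"].astype(float),
        },
        index=env.index,
    )
    scaled = minmax_scale(harsh)
    res = noncentred_pca(scaled.to_numpy())
    score = res.scores[:, 0]
    if np.ptp(score) == 0:
        raise ValueError("axis-1 scores constant; glaciality orientation undefined")
    # glacial sites have uniformly LOW scaled harshness variables, so the
    # index must anti-correlate with the row mean of the scaled matrix
    rowmean = scaled.to_numpy().mean(axis=1)
    if np.corrcoef(score, rowmean)[0, 1] > 0:
        score = -score
    score = score - score.min()
    return pd.Series(score, index=env.index, name="glaciality")


def assign_segment_glaciality(
    network: StreamNetwork, index: pd.Series
) -> StreamNetwork:
    """Attribute a glaciality value to every segment of the network.

    A segment takes the index of the nearest site reached by walking
    upstream along its own branch (no tributary junction in between);
    segments immediately downstream of a confluence, which have no single
    upstream site on their branch, take the nearest *downstream* site's
    value instead.  Re-running is idempotent.
    """
    g = network.graph
    is_site = network.node_attr("is_site")
    idx = {k: float(v) for k, v in index.items()}

    def nearest_upstream_site(node):
        # follow the single-branch chain upstream until a site or a junction
        cur = node
        while True:
            if is_site.get(cur) and cur in idx:
                return cur
            preds = list(g.predecessors(cur))
            if len(preds) != 1:
                return None  # headwater non-site or confluence: no single branch
            cur = preds[0]

    def nearest_downstream_site(node):
        cur = node
        while cur is not None:
            if is_site.get(cur) and cur in idx:
                return cur
            succ = list(g.successors(cur))
            cur = succ[0] if succ else None
        return None

    values = {}
    for row in network.segments.itertuples(index=False):
        site = nearest_upstream_site(row.up_node)
        if site is None:
            site = nearest_downstream_site(row.down_node)
        if site is None:
            raise ValueError(
                f"segment {row.segment_id!r} has no attributable site "
                "upstream or downstream"
            )
        values[row.segment_id] = idx[site]
    network.set_segment_glaciality(values)
    return network


def glaciality_distance_matrix(
    network: StreamNetwork, index: pd.Series, *, allow_missing: bool = True
) -> DistanceMatrix:
    """Glaciality range encountered along the channel between site pairs.

    d_ij = max − min over the glaciality of every segment on the tree path
    between i and j together with the two endpoint site indices (so that
    d_ii = 0 and d_ij ≥ |index_i − index_j|).
    """
    if network.segments["glaciality"].isna().any() if "glaciality" in network.segments else True:
        raise ValueError("segments not attributed; run assign_segment_glaciality first")
    labels = network.site_ids
    und = network.undirected()
    idx = {k: float(v) for k, v in index.items()}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = labels[i], labels[j]
            try:
                path = nx.shortest_path(und, a, b)
            except nx.NetworkXNoPath:
                if not allow_missing:
                    raise ValueError(f"sites {a!r}, {b!r} disconnected") from None
                d[i, j] = d[j, i] = np.nan
                continue
            vals = [idx[a], idx[b]]
            for u, v in zip(path[:-1], path[1:]):
                data = und.get_edge_data(u, v)
                vals.append(float(data["glaciality"]))
            d[i, j] = d[j, i] = max(vals) - min(vals)
    return DistanceMatrix(d, labels, "watercourse_gla")
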