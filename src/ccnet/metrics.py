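"""Graph-topology metrics for thresholded structural connectomes.

Four metrics drive the group analysis:

* **average degree** — mean number of binary connections per node,
  ``2|E| / n``; a basic integration measure.
* **average clustering coefficient** — segregation; the binary form is the
  fraction of a node's neighbour pairs that are themselves connected,
  averaged over nodes.  Weighted variants (Onnela geometric-mean-of-triangle
  weights, Barrat strength-weighted) are selectable and reduce to the
  binary form on unit weights.
* **global efficiency** — mean inverse shortest-path length over all node
  pairs, with edge distance ``d = 1/w`` by default; disconnected pairs
  contribute zero.
* **betweenness centrality** — fraction of all-pairs weighted geodesics
  passing through a node (Brandes accumulation), compared node-wise between
  groups at a single fixed density.

Clustering and betweenness are implemented from first principles (the test
suite checks them against exhaustive path/triangle enumeration and against
networkx); shortest paths use Dijkstra from :mod:`scipy.sparse.csgraph`.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from ._errors import DataError, InvalidParameterError
from .connectome import DEFAULT_DENSITIES, ThresholdedGraph, WeightedNetwork, density_sweep

GLOBAL_METRICS = ("clustering", "degree", "efficiency")

#: Density at which node-level betweenness is compared between groups.
BETWEENNESS_DENSITY = 0.50


def average_degree(g: ThresholdedGraph) -> float:
    """Mean binary degree ``2|E| / n`` (weights ignored)."""
    return 2.0 * g.n_edges / g.n_nodes


def average_clustering(g: ThresholdedGraph, variant: str = "binary") -> float:
    """Average clustering coefficient; nodes with degree < 2 contribute 0."""
    a = (g.weights > 0).astype(float)
    k = a.sum(axis=1)
    denom = k * (k - 1)
    ok = denom > 0
    if variant == "binary":
        tri = np.diag(a @ a @ a)  # 2 * number of closed neighbour pairs
        c = np.zeros(g.n_nodes)
        c[ok] = tri[ok] / denom[ok]
    elif variant == "onnela":
        wmax = g.weights.max()
        if wmax <= 0:
            return 0.0
        wh = np.cbrt(g.weights / wmax)
        tri = np.diag(wh @ wh @ wh)
        c = np.zeros(g.n_nodes)
        c[ok] = tri[ok] / denom[ok]
    elif variant == "barrat":
        w, s = g.weights, g.weights.sum(axis=1)
        # sum over connected neighbour pairs (j, h) of (w_ij + w_ih) / 2
        cw = np.diag((w @ a @ a) + (a @ a @ w)) / 2.0
        c = np.zeros(g.n_nodes)
        okb = ok & (s > 0)
        c[okb] = cw[okb] / (s[okb] * (k[okb] - 1))
    else:
        raise InvalidParameterError(f"unknown clustering variant {variant!r}")
    return float(c.mean())


def _distance_matrix(g: ThresholdedGraph, distance_rule="inverse") -> np.ndarray:
    """Edge weights mapped to positive distances (default ``d = 1/w``)."""
    w = g.weights
    mask = w != 0
    if np.any(w[mask] < 0):
        raise DataError("retained edge with non-positive weight")
    d = np.zeros_like(w)
    if distance_rule == "inverse":
        d[mask] = 1.0 / w[mask]
    elif callable(distance_rule):
        d[mask] = distance_rule(w[mask])
        if np.any(d[mask] <= 0):
            raise DataError("distance rule produced a non-positive distance")
    else:
        raise InvalidParameterError(f"unknown distance rule {distance_rule!r}")
    return d


def shortest_path_lengths(g: ThresholdedGraph, distance_rule="inverse") -> np.ndarray:
    """All-pairs geodesic distances (Dijkstra per source); inf off-component."""
    d = _distance_matrix(g, distance_rule)
    return dijkstra(csr_matrix(d), directed=False)


def global_efficiency(g: ThresholdedGraph, distance_rule="inverse") -> float:
    """Mean of inverse geodesic distances over unordered node pairs."""
    n = g.n_nodes
    if n < 2:
        return 0.0
    sp = shortest_path_lengths(g, distance_rule)
    iu = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(sp[iu]) & (sp[iu] > 0), 1.0 / sp[iu], 0.0)
    return float(inv.mean())


def betweenness_all(
    g: ThresholdedGraph, distance_rule="inverse", normalised: bool = False
) -> np.ndarray:
    """Weighted betweenness centrality of every node (Brandes' algorithm).

    Endpoint pairs are excluded; for an undirected graph each unordered
    pair is counted once.  With ``normalised`` the counts are divided by
    ``(n-1)(n-2)/2``.
    """
    n = g.n_nodes
    dmat = _distance_matrix(g, distance_rule)
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for i in range(n):
        nz = np.nonzero(dmat[i])[0]
        adj[i] = [(int(j), float(dmat[i, j])) for j in nz]
    bc = np.zeros(n)
    for s in range(n):
        dist = np.full(n, np.inf)
        sigma = np.zeros(n)
        dist[s], sigma[s] = 0.0, 1.0
        pred: list[list[int]] = [[] for _ in range(n)]
        done = np.zeros(n, dtype=bool)
        order: list[int] = []
        heap: list[tuple[float, int]] = [(0.0, s)]
        while heap:
            dv, v = heapq.heappop(heap)
            if done[v]:
                continue
            done[v] = True
            order.append(v)
            for u, duv in adj[v]:
                alt = dv + duv
                if alt < dist[u]:
                    dist[u] = alt
                    sigma[u] = sigma[v]
                    pred[u] = [v]
                    heapq.heappush(heap, (alt, u))
                elif alt == dist[u] and not done[u]:
                    sigma[u] += sigma[v]
                    pred[u].append(v)
        delta = np.zeros(n)
        for v in reversed(order):
            for p in pred[v]:
                delta[p] += sigma[p] / sigma[v] * (1.0 + delta[v])
            if v != s:
                bc[v] += delta[v]
    bc /= 2.0  # each unordered pair visited from both endpoints
    if normalised:
        if n > 2:
            bc /= (n - 1) * (n - 2) / 2.0
    return bc


def induced_subgraph(g: ThresholdedGraph, node_subset) -> ThresholdedGraph:
    """Subgraph on ``node_subset`` keeping edges with both endpoints inside."""
    if len(node_subset) == 0:
        raise InvalidParameterError("node subset must be non-empty")
    idx = []
    for lab in node_subset:
        if lab not in g.labels:
            raise DataError(f"unknown node label {lab!r}")
        idx.append(g.labels.index(lab))
    idx = np.asarray(idx)
    return ThresholdedGraph(
        weights=g.weights[np.ix_(idx, idx)],
        density=g.density,
        labels=tuple(g.labels[i] for i in idx),
        subject_id=g.subject_id,
    )


def subnetwork_metrics(
    g: ThresholdedGraph, node_subset, clustering_variant: str = "binary"
) -> dict[str, float]:
    """Degree, clustering and efficiency on the induced subgraph."""
    sub = induced_subgraph(g, node_subset)
    return {
        "degree": average_degree(sub),
        "clustering": average_clustering(sub, clustering_variant),
        "efficiency": global_efficiency(sub),
    }


# ---------------------------------------------------------------------------
# subject x (metric, density) tables


@dataclass
class MetricTable:
    """Subject-by-(metric, density) values, raw or z-standardised.

    ``data`` carries a two-level column index ``(metric, density)``; the
    ``kind`` flag records whether values are raw or pooled-z.
    """

    data: pd.DataFrame
    kind: str = "raw"

    def to_csv(self, path) -> None:
        self.data.to_csv(path)

    @classmethod
    def from_csv(cls, path, kind: str = "raw") -> "MetricTable":
        df = pd.read_csv(path, header=[0, 1], index_col=0)
        df.columns = pd.MultiIndex.from_tuples(
            [(m, float(d)) for m, d in df.columns], names=["metric", "density"]
        )
        return cls(data=df, kind=kind)


def compute_metric_table(
    networks: list[WeightedNetwork],
    densities: tuple[float, ...] = DEFAULT_DENSITIES,
    clustering_variant: str = "binary",
    node_subset=None,
) -> MetricTable:
    """Density sweep + the three global metrics for every subject.

    With ``node_subset`` the metrics are computed on the induced subgraph
    of each thresholded graph (the full network is thresholded first, as
    in the subcortical-subnetwork analysis).
    """
    rows = {}
    for net in networks:
        vals = {}
        for g in density_sweep(net, densities):
            if node_subset is not None:
                g = induced_subgraph(g, node_subset)
            vals[("clustering", g.density)] = average_clustering(g, clustering_variant)
            vals[("degree", g.density)] = average_degree(g)
            vals[("efficiency", g.density)] = global_efficiency(g)
        rows[net.subject_id] = vals
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["metric", "density"])
    df = df.sort_index(axis=1)
    return MetricTable(data=df, kind="raw")


def compute_betweenness_table(
    networks: list[WeightedNetwork],
    density: float = BETWEENNESS_DENSITY,
    normalised: bool = False,
) -> pd.DataFrame:
    """Per-node betweenness for every subject at one fixed density."""
    rows = {}
    for net in networks:
        g = density_sweep(net, (density,))[0]
        rows[net.subject_id] = betweenness_all(g, normalised=normalised)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(networks[0].labels)
    )


def zstandardise(t: MetricTable | pd.DataFrame, ddof: int = 1, on_constant: str = "error"):
    """Column-wise z-scores pooled over all subjects (sample SD).

    Pooling across both groups forces each column's weighted mean to zero,
    so group means sit on opposite sides of zero.  A zero-variance column
    is an error by default; ``on_constant="zero"`` maps it to all-zero
    instead (proportional thresholding makes degree constant at densities
    every subject's edge count saturates, which is expected, not a fault).
    """
    df = t.data if isinstance(t, MetricTable) else t
    sd = df.std(ddof=ddof)
    zero = sd[sd == 0]
    if len(zero) > 0:
        if on_constant == "error":
            raise DataError(f"zero-variance column(s): {list(zero.index)}")
        warnings.warn(
            f"constant column(s) mapped to zero: {list(zero.index)}", stacklevel=2
        )
        sd = sd.replace(0, 1.0)
    z = (df - df.mean()) / sd
    if isinstance(t, MetricTable):
        return MetricTable(data=z, kind="z")
    return z


def aggregate_densities(t: MetricTable) -> pd.DataFrame:
    """Arithmetic mean across the density grid -> one value per metric."""
    df = t.data
    if df.isna().any().any():
        missing = sorted(
            {c for c in df.columns[df.isna().any()]}
        )
        raise DataError(f"missing values in density grid columns: {missing}")
    return df.T.groupby(level="metric").mean().T
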