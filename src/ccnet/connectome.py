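"""Turn raw streamline-count/tract-length matrices into weighted networks.

A structural connectome arrives as two square matrices per subject: a
non-negative streamline count matrix (not necessarily symmetric, because
probabilistic tractography is seeded per region) and a strictly positive
symmetric tract-length matrix.  The pipeline normalises counts by tract
length, symmetrises by averaging the two triangles, and then applies
proportional thresholding: at density ``t`` the ``K = ceil(t * n(n-1)/2)``
strongest edges are retained with their weights.  A sweep over a density
grid yields one thresholded graph per density with nested edge sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import DataError, InvalidParameterError

#: Density grid used throughout: 5% to 50% in 5% steps -> ten graphs/subject.
DEFAULT_DENSITIES: tuple[float, ...] = tuple(round(0.05 * k, 2) for k in range(1, 11))


@dataclass
class RawConnectome:
    """Per-subject tractography output: streamline counts and tract lengths.

    ``counts[i, j]`` is the number of streamlines seeded in region ``i``
    reaching region ``j`` (diagonal zero); ``lengths`` is the symmetric
    matrix of mean tract lengths, strictly positive wherever a streamline
    exists in either orientation.
    """

    counts: np.ndarray
    lengths: np.ndarray
    labels: tuple[str, ...]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.labels = tuple(self.labels)
        n = len(self.labels)
        if self.counts.shape != (n, n) or self.lengths.shape != (n, n):
            raise DataError(
                f"subject {self.subject_id!r}: matrices must be {n}x{n} "
                f"to match {n} region labels"
            )
        if np.any(self.counts < 0):
            raise DataError(f"subject {self.subject_id!r}: negative streamline count")
        if np.any(np.diag(self.counts) != 0):
            raise DataError(f"subject {self.subject_id!r}: count diagonal must be 0")
        if not np.allclose(self.lengths, self.lengths.T):
            raise DataError(f"subject {self.subject_id!r}: length matrix not symmetric")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)


@dataclass
class WeightedNetwork:
    """Symmetric weighted adjacency with zero diagonal and region labels."""

    weights: np.ndarray
    labels: tuple[str, ...]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.labels = tuple(self.labels)
        n = len(self.labels)
        if self.weights.shape != (n, n):
            raise DataError("weight matrix shape does not match labels")
        if not np.all(np.isfinite(self.weights)):
            raise DataError("non-finite edge weight")
        if not np.allclose(self.weights, self.weights.T):
            raise DataError("weight matrix not symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise DataError("weight diagonal must be 0")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def positive_edge_count(self) -> int:
        iu = np.triu_indices(self.n_nodes, k=1)
        return int(np.count_nonzero(self.weights[iu] > 0))


@dataclass
class ThresholdedGraph:
    """A density-thresholded view of a :class:`WeightedNetwork`.

    ``weights`` holds the retained edges (original weights, no
    binarisation); everything else is zero.
    """

    weights: np.ndarray
    density: float
    labels: tuple[str, ...]
    subject_id: str = ""
    parent: WeightedNetwork | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.n_nodes, k=1)
        return int(np.count_nonzero(self.weights[iu] > 0))

    def achieved_density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)

    def edge_list(self) -> pd.DataFrame:
        """Retained edges as a three-column table (node_i, node_j, weight)."""
        i, j = np.nonzero(np.triu(self.weights, k=1))
        return pd.DataFrame(
            {
                "node_i": [self.labels[a] for a in i],
                "node_j": [self.labels[b] for b in j],
                "weight": self.weights[i, j],
            }
        )


def normalise_weights(raw: RawConnectome) -> np.ndarray:
    """Divide each raw streamline count by the corresponding tract length.

    Zero counts stay zero; a positive count paired with a non-positive
    length is a data error (the offending cell is named).
    """
    counts, lengths = raw.counts, raw.lengths
    bad = (counts > 0) & (lengths <= 0)
    if np.any(bad):
        i, j = map(int, np.argwhere(bad)[0])
        raise DataError(
            f"subject {raw.subject_id!r}: positive count at "
            f"({raw.labels[i]}, {raw.labels[j]}) but non-positive tract length"
        )
    out = np.zeros_like(counts, dtype=float)
    pos = counts > 0
    out[pos] = counts[pos] / lengths[pos]
    np.fill_diagonal(out, 0.0)
    return out


def symmetrise(
    m: np.ndarray, labels: tuple[str, ...] | None = None, subject_id: str = ""
) -> WeightedNetwork:
    """Average the upper and lower triangles and zero the diagonal."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise DataError(f"symmetrise expects a square matrix, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise DataError("symmetrise expects finite entries")
    w = 0.5 * (m + m.T)
    np.fill_diagonal(w, 0.0)
    if labels is None:
        labels = tuple(f"n{i}" for i in range(m.shape[0]))
    return WeightedNetwork(weights=w, labels=labels, subject_id=subject_id)


def build_network(raw: RawConnectome) -> WeightedNetwork:
    """Full build: length-normalise then symmetrise a raw connectome."""
    return symmetrise(normalise_weights(raw), raw.labels, raw.subject_id)


def _ranked_edges(net: WeightedNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Positive edges ranked by descending weight, ties by (i, j) index."""
    n = net.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    w = net.weights[iu, ju]
    pos = w > 0
    iu, ju, w = iu[pos], ju[pos], w[pos]
    order = np.lexsort((ju, iu, -w))  # primary: -w, then i, then j
    return iu[order], ju[order]


def threshold_proportional(net: WeightedNetwork, density: float) -> ThresholdedGraph:
    """Retain the top-``K`` edges at the requested density.

    ``K = ceil(density * n(n-1)/2)``; if the network has fewer positive
    edges than ``K``, all of them are retained (edges are never invented).
    Weight ties are broken by lexicographic node-index order so the result
    is platform-independent and sweeps are nested.
    """
    if not 0 < density <= 1:
        raise InvalidParameterError(f"density must be in (0, 1], got {density}")
    n = net.n_nodes
    e_max = n * (n - 1) // 2
    k = math.ceil(density * e_max)
    ri, rj = _ranked_edges(net)
    keep = min(k, ri.size)
    out = np.zeros_like(net.weights)
    sel_i, sel_j = ri[:keep], rj[:keep]
    out[sel_i, sel_j] = net.weights[sel_i, sel_j]
    out[sel_j, sel_i] = net.weights[sel_i, sel_j]
    return ThresholdedGraph(
        weights=out,
        density=float(density),
        labels=net.labels,
        subject_id=net.subject_id,
        parent=net,
    )


def density_sweep(
    net: WeightedNetwork, densities: tuple[float, ...] = DEFAULT_DENSITIES
) -> list[ThresholdedGraph]:
    """One thresholded graph per density; edge sets are nested by design."""
    if len(densities) == 0:
        raise InvalidParameterError("density grid must be non-empty")
    return [threshold_proportional(net, d) for d in densities]
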