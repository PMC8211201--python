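"""Global network measures and modularity-maximizing community detection.

Graph density and the global clustering coefficient (transitivity) are
computed on the binarized graph — an edge exists wherever the association
index is positive — because both definitions count edges, not weights.
Modularity and community detection use the index weights.

Community detection is greedy agglomerative modularity maximization
(Clauset–Newman–Moore "fast greedy"), delegated to igraph's C
implementation: singleton communities are merged pairwise by maximal
modularity gain and the partition at the modularity peak of the merge
path is returned. The algorithm is deterministic for a fixed input.
"""

from __future__ import annotations

import numpy as np
import igraph as ig

from .association import AssociationMatrix
from .datatypes import GlobalMetrics, Partition


def _check_symmetric(m: AssociationMatrix) -> np.ndarray:
    w = np.asarray(m.w, dtype=float)
    if not np.allclose(w, w.T):
        raise ValueError("association matrix must be symmetric")
    return w


def graph_density(m: AssociationMatrix) -> float:
    """Fraction of possible dyads with a positive association index."""
    w = _check_symmetric(m)
    n = m.n
    if n < 2:
        raise ValueError("graph density is undefined for fewer than 2 nodes")
    iu = np.triu_indices(n, 1)
    return float(np.count_nonzero(w[iu] > 0) / (n * (n - 1) / 2))


def global_clustering(m: AssociationMatrix) -> float:
    """Transitivity of the binarized graph: 3 x triangles / connected triples."""
    w = _check_symmetric(m)
    n = m.n
    if n < 3:
        raise ValueError("clustering coefficient is undefined for fewer than 3 nodes")
    a = (w > 0).astype(np.float64)
    np.fill_diagonal(a, 0.0)
    deg = a.sum(axis=1)
    triples = float((deg * (deg - 1)).sum() / 2.0)
    if triples == 0:
        return 0.0
    triangles = float(np.trace(a @ a @ a) / 6.0)
    return 3.0 * triangles / triples


def modularity(m: AssociationMatrix, p: Partition) -> float:
    """Weighted Newman modularity of partition ``p`` on network ``m``.

    Q = sum_c [ W_c / W - (s_c / 2W)^2 ] with W the total edge weight,
    W_c the within-community weight and s_c the total strength of
    community c. Returns 0 for an edgeless matrix (degenerate case).
    """
    w = _check_symmetric(m)
    labels = p.label_array(m.ids)
    strength = w.sum(axis=1)
    total = strength.sum()  # = 2W
    if total == 0:
        return 0.0
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        w_in = w[np.ix_(mask, mask)].sum()  # = 2 * within weight
        s_c = strength[mask].sum()
        q += w_in / total - (s_c / total) ** 2
    return float(q)


def _to_igraph(w: np.ndarray) -> tuple[ig.Graph, np.ndarray]:
    n = w.shape[0]
    iu = np.triu_indices(n, 1)
    mask = w[iu] > 0
    edges = np.column_stack((iu[0][mask], iu[1][mask]))
    g = ig.Graph(n=n, edges=edges.tolist())
    return g, w[iu][mask]


def fast_greedy_communities(m: AssociationMatrix) -> Partition:
    """Greedy agglomerative modularity maximization on the weighted network.

    An edgeless matrix yields the all-singleton partition with Q = 0 and
    the ``degenerate`` flag set (the defined outcome for disconnected
    sample networks).
    """
    w = _check_symmetric(m)
    n = m.n
    g, weights = _to_igraph(w)
    if g.ecount() == 0:
        labels = {ident: i for i, ident in enumerate(m.ids)}
        return Partition(labels=labels, q=0.0, degenerate=True)
    clustering = g.community_fastgreedy(weights=list(weights)).as_clustering()
    labels = {ident: int(memb) for ident, memb in zip(m.ids, clustering.membership)}
    part = Partition(labels=labels, q=0.0, degenerate=False)
    part.q = modularity(m, part)
    return part


def global_metrics(m: AssociationMatrix, partition: Partition | None = None) -> GlobalMetrics:
    """Density, clustering, and detected-partition modularity in one call."""
    if partition is None:
        partition = fast_greedy_communities(m)
    return GlobalMetrics(
        q=partition.q,
        n_communities=partition.n_communities,
        density=graph_density(m),
        clustering=global_clustering(m),
    )
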