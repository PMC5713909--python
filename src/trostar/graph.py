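"""Markov-random-field neighbourhood structure over schools.

Schools are point-referenced, so the intrinsic-CAR neighbourhood has to be
derived from coordinates.  Two standard surrogates are provided: Delaunay
triangulation edges (default) and symmetrised k-nearest-neighbour edges.
The ICAR precision matrix is the graph Laplacian Q = D - A, which penalises
squared differences between neighbouring schools and has a one-dimensional
null space (the constants) on a connected graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import Delaunay, distance_matrix


@dataclass
class SpatialGraph:
    """School adjacency structure and its ICAR precision matrix.

    Attributes
    ----------
    node_ids : list
        School identifiers, in the row/column order of ``Q``.
    neighbors : list of list of int
        Per-node neighbour indices (positions into ``node_ids``).
    Q : ndarray
        Graph Laplacian: ``Q[i, i] = degree(i)``, ``Q[i, j] = -1`` if
        ``i ~ j`` else 0.  Symmetric; every row sums to zero.
    """

    node_ids: list
    neighbors: list[list[int]] = field(repr=False)
    Q: np.ndarray = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def edges(self) -> list[tuple[int, int]]:
        """Undirected edge list as (i, j) index pairs with i < j."""
        out = []
        for i, nbrs in enumerate(self.neighbors):
            for j in nbrs:
                if i < j:
                    out.append((i, j))
        return out

    def quadratic_form(self, f: np.ndarray) -> float:
        """f' Q f, the ICAR roughness penalty."""
        f = np.asarray(f, dtype=float)
        if f.shape[-1] != self.n_nodes:
            raise ValueError(
                f"f has length {f.shape[-1]}, graph has {self.n_nodes} nodes"
            )
        return float(f @ self.Q @ f)

    def generalized_log_det(self) -> float:
        """Log pseudo-determinant of Q (product of nonzero eigenvalues)."""
        ev = np.linalg.eigvalsh(self.Q)
        nz = ev[ev > 1e-10 * max(ev.max(), 1.0)]
        return float(np.sum(np.log(nz)))

    def to_edge_csv(self, path) -> None:
        """Export the edge list as a two-column CSV (school_id_a, school_id_b)."""
        import pandas as pd

        rows = [
            {"school_id_a": self.node_ids[i], "school_id_b": self.node_ids[j]}
            for i, j in self.edges
        ]
        pd.DataFrame(rows, columns=["school_id_a", "school_id_b"]).to_csv(
            path, index=False
        )


def _check_distinct(ids: Sequence, xy: np.ndarray) -> None:
    dmat = distance_matrix(xy, xy)
    np.fill_diagonal(dmat, np.inf)
    dup = np.argwhere(dmat < 1e-12)
    if dup.size:
        i, j = dup[0]
        raise ValueError(
            f"duplicate coordinates for schools {ids[int(i)]!r} and {ids[int(j)]!r}"
        )


def _components(n: int, adj: np.ndarray) -> list[np.ndarray]:
    """Connected components by BFS on a boolean adjacency matrix."""
    seen = np.zeros(n, dtype=bool)
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in np.flatnonzero(adj[u]):
                if not seen[v]:
                    seen[v] = True
                    stack.append(int(v))
        comps.append(np.asarray(comp))
    return comps


def _bridge_components(adj: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Join the two closest nodes of distinct components until connected."""
    n = adj.shape[0]
    while True:
        comps = _components(n, adj)
        if len(comps) == 1:
            return adj
        # closest pair between the first component and any other
        best = None
        a = comps[0]
        for other in comps[1:]:
            d = distance_matrix(xy[a], xy[other])
            k = np.unravel_index(np.argmin(d), d.shape)
            cand = (d[k], a[k[0]], other[k[1]])
            if best is None or cand[0] < best[0]:
                best = cand
        _, i, j = best
        adj[i, j] = adj[j, i] = True


def build_graph(schools, method: str = "delaunay", k: int = 4) -> SpatialGraph:
    """Build the school neighbourhood graph and its ICAR precision matrix.

    Parameters
    ----------
    schools : sequence of SchoolRecord (or anything with school_id, x_km, y_km)
    method : {"delaunay", "knn"}
        Delaunay triangulation edges, or symmetrised k-nearest neighbours.
    k : int
        Number of neighbours for ``method="knn"``; must be < number of schools.

    If the resulting graph is disconnected, the two closest nodes of
    distinct components are joined iteratively until it is connected, so Q
    always has rank n - 1.
    """
    ids = [s.school_id for s in schools]
    xy = np.asarray([[s.x_km, s.y_km] for s in schools], dtype=float)
    n = len(ids)
    if n < 3:
        raise ValueError(f"need at least 3 schools, got {n}")
    _check_distinct(ids, xy)

    adj = np.zeros((n, n), dtype=bool)
    if method == "delaunay":
        tri = Delaunay(xy)
        for simplex in tri.simplices:
            for a in range(3):
                i, j = simplex[a], simplex[(a + 1) % 3]
                adj[i, j] = adj[j, i] = True
    elif method == "knn":
        if k >= n:
            raise ValueError(f"k={k} must be smaller than the number of schools ({n})")
        dmat = distance_matrix(xy, xy)
        np.fill_diagonal(dmat, np.inf)
        for i in range(n):
            for j in np.argsort(dmat[i])[:k]:
                adj[i, j] = adj[j, i] = True
    else:
        raise ValueError(f"unknown method {method!r}")

    adj = _bridge_components(adj, xy)
    np.fill_diagonal(adj, False)

    A = adj.astype(float)
    Q = np.diag(A.sum(axis=1)) - A
    neighbors = [list(np.flatnonzero(adj[i])) for i in range(n)]
    return SpatialGraph(node_ids=ids, neighbors=neighbors, Q=Q)


def icar_logpdf(f: np.ndarray, tau2: float, graph: SpatialGraph) -> float:
    """Improper ICAR log-density of a spatial field, rank n-1 convention.

    log p(f | tau2) = -f'Qf / (2 tau2) - ((n-1)/2) log(tau2)
                      + (1/2) log gdet(Q) - ((n-1)/2) log(2 pi)

    where gdet is the generalized (pseudo-)determinant.  The density is
    improper: it is invariant to adding a constant to ``f``.
    """
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    f = np.asarray(f, dtype=float)
    if f.shape != (graph.n_nodes,):
        raise ValueError(
            f"f has shape {f.shape}, expected ({graph.n_nodes},)"
        )
    n = graph.n_nodes
    quad = graph.quadratic_form(f)
    return (
        -quad / (2.0 * tau2)
        - 0.5 * (n - 1) * np.log(tau2)
        + 0.5 * graph.generalized_log_det()
        - 0.5 * (n - 1) * np.log(2.0 * np.pi)
    )
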