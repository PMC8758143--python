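"""Neurite skeletons as spatial trees.

A :class:`SkeletonGraph` is the geometric substrate for all AIS analyses: a
connected, acyclic graph of 3D nodes (positions in nm) with per-node radii,
typically produced upstream by mesh skeletonization and consumed here from
SWC files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components, dijkstra

__all__ = ["SkeletonGraph", "read_swc", "write_swc"]


@dataclass
class SkeletonGraph:
    """A neurite as a spatial tree.

    Parameters
    ----------
    positions : (n, 3) float array
        Node positions in nm.
    radii : (n,) float array
        Node radii in nm.
    edges : (m, 2) int array
        Parent-child pairs as row indices into ``positions``. Every edge must
        have strictly positive length; the graph must be connected and
        acyclic.
    node_ids : (n,) int array, optional
        External node identifiers (defaults to 0..n-1).
    """

    positions: np.ndarray
    radii: np.ndarray
    edges: np.ndarray
    node_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int)
        if self.node_ids is None:
            self.node_ids = np.arange(len(self.positions))
        else:
            self.node_ids = np.asarray(self.node_ids, dtype=int)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        n = len(self.positions)
        if self.edges.size and (self.edges.min() < 0 or self.edges.max() >= n):
            raise ValueError("edge index out of range")
        lengths = self.edge_lengths()
        if np.any(lengths <= 0):
            raise ValueError("every edge must have length > 0")
        if len(self.edges) != n - 1:
            raise ValueError("a tree on n nodes must have n-1 edges")
        n_comp, _ = connected_components(self.adjacency(), directed=False)
        if n_comp != 1:
            raise ValueError("skeleton must be connected")

    def __len__(self) -> int:
        return len(self.positions)

    def edge_lengths(self) -> np.ndarray:
        if not self.edges.size:
            return np.empty(0)
        d = self.positions[self.edges[:, 0]] - self.positions[self.edges[:, 1]]
        return np.linalg.norm(d, axis=1)

    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric weighted adjacency matrix (edge weights = lengths, nm)."""
        n = len(self)
        if not self.edges.size:
            return sparse.csr_matrix((n, n))
        w = self.edge_lengths()
        i, j = self.edges[:, 0], self.edges[:, 1]
        mat = sparse.coo_matrix(
            (np.r_[w, w], (np.r_[i, j], np.r_[j, i])), shape=(n, n)
        )
        return mat.tocsr()

    def geodesic_from(self, index: int) -> np.ndarray:
        """Geodesic (along-skeleton) distance in nm from one node to all."""
        return dijkstra(self.adjacency(), directed=False, indices=index)

    def nearest_node(self, point) -> int:
        """Index of the node closest (Euclidean) to a 3D point in nm."""
        d = np.linalg.norm(self.positions - np.asarray(point, float), axis=1)
        return int(np.argmin(d))


def read_swc(path) -> SkeletonGraph:
    """Read a standard 7-column SWC file (id, type, x, y, z, radius, parent).

    Coordinates and radii are interpreted as nm. Type codes are ignored.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"malformed SWC line: {line!r}")
            rows.append(parts)
    if not rows:
        raise ValueError(f"empty SWC file: {path}")
    df = pd.DataFrame(rows, columns=["id", "type", "x", "y", "z", "r", "parent"])
    ids = df["id"].astype(int).to_numpy()
    order = {nid: i for i, nid in enumerate(ids)}
    pos = df[["x", "y", "z"]].astype(float).to_numpy()
    radii = df["r"].astype(float).to_numpy()
    parents = df["parent"].astype(int).to_numpy()
    edges = [
        (order[p], order[c]) for c, p in zip(ids, parents) if p != -1
    ]
    return SkeletonGraph(
        positions=pos, radii=radii, edges=np.asarray(edges, int).reshape(-1, 2),
        node_ids=ids,
    )


def write_swc(skel: SkeletonGraph, path, node_type: int = 2) -> None:
    """Write a skeleton as standard 7-column SWC (nm units)."""
    parent = np.full(len(skel), -1, dtype=int)
    # orient edges away from node 0 via BFS so parents precede children
    adj = [[] for _ in range(len(skel))]
    for i, j in skel.edges:
        adj[i].append(j)
        adj[j].append(i)
    seen = np.zeros(len(skel), bool)
    stack = [0]
    seen[0] = True
    order = []
    while stack:
        u = stack.pop()
        order.append(u)
        for v in adj[u]:
            if not seen[v]:
                seen[v] = True
                parent[v] = u
                stack.append(v)
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent (nm)\n")
        for u in order:
            p = skel.node_ids[parent[u]] if parent[u] >= 0 else -1
            x, y, z = skel.positions[u]
            fh.write(
                f"{skel.node_ids[u]} {node_type} {x:.3f} {y:.3f} {z:.3f} "
                f"{skel.radii[u]:.3f} {p}\n"
            )
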