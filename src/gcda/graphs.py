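"""Undirected, unweighted graphs over a fixed gene set.

Gene regulatory networks (GRNs) are modelled as finite simple graphs: vertices
are genes, edges are interactions.  The graph enters the classifier through
its Laplacian ``L = D - A`` (degrees on the diagonal, -1 on edges), which is
positive semi-definite with zero row sums and is the ingredient of the
graph-derived covariance shrinkage target.

Graphs are unweighted by design: a weighted adjacency matrix is rejected
unless explicitly binarized, because the Laplacian used downstream is defined
for 0/1 edges only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "Graph",
    "empty_graph",
    "laplacian",
    "erdos_renyi",
    "rewire",
    "structural_hamming_distance",
    "read_edge_list",
    "write_edge_list",
    "read_adjacency",
]


def _normalize_edge(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


@dataclass(frozen=True)
class Graph:
    """Simple undirected graph on ``n_vertices`` labelled vertices.

    Parameters
    ----------
    n_vertices
        Number of vertices ``p`` (genes).
    edges
        Unordered vertex pairs; stored normalized as ``(min, max)``.
    vertex_labels
        Optional gene identifiers, one per vertex, all unique.
    """

    n_vertices: int
    edges: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    vertex_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_vertices < 1:
            raise ValueError(f"n_vertices must be positive, got {self.n_vertices}")
        norm = set()
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop at vertex {i}")
            if not (0 <= i < self.n_vertices and 0 <= j < self.n_vertices):
                raise ValueError(f"edge ({i}, {j}) outside [0, {self.n_vertices})")
            norm.add(_normalize_edge(i, j))
        object.__setattr__(self, "edges", frozenset(norm))
        if self.vertex_labels is not None:
            labels = tuple(self.vertex_labels)
            if len(labels) != self.n_vertices:
                raise ValueError("vertex_labels length must equal n_vertices")
            if len(set(labels)) != len(labels):
                raise ValueError("vertex_labels must be unique")
            object.__setattr__(self, "vertex_labels", labels)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_vertices, dtype=int)
        for i, j in self.edges:
            d[i] += 1
            d[j] += 1
        return d

    def adjacency(self) -> np.ndarray:
        A = np.zeros((self.n_vertices, self.n_vertices))
        for i, j in self.edges:
            A[i, j] = A[j, i] = 1.0
        return A

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_vertices))
        g.add_edges_from(self.edges)
        return g


def empty_graph(p: int, vertex_labels=None) -> Graph:
    """Graph on ``p`` vertices with no edges (identity-style shrinkage target)."""
    return Graph(p, frozenset(), vertex_labels)


def laplacian(g: Graph) -> np.ndarray:
    """Graph Laplacian ``L = D - A``.

    ``L[i, i]`` is the connectivity degree of vertex ``i``; ``L[i, j] = -1``
    iff ``(i, j)`` is an edge, 0 otherwise.  Symmetric, positive semi-definite,
    zero row sums.
    """
    L = np.zeros((g.n_vertices, g.n_vertices))
    for i, j in g.edges:
        L[i, j] = L[j, i] = -1.0
        L[i, i] += 1.0
        L[j, j] += 1.0
    return L


def erdos_renyi(p: int, edge_prob: float, seed) -> Graph:
    """Erdős–Rényi G(p, q) graph: each of the p(p-1)/2 pairs is an edge
    independently with probability ``edge_prob``.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if p < 1:
        raise ValueError(f"p must be positive, got {p}")
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError(f"edge_prob must be in [0, 1], got {edge_prob}")
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(p, edge_prob, seed=rng)
    return Graph(p, frozenset(_normalize_edge(i, j) for i, j in g.edges))


def rewire(g: Graph, n_moves: int, seed) -> Graph:
    """Randomly reassign ``n_moves`` distinct edges to currently absent pairs.

    Each selected edge is removed and replaced by a uniformly drawn vertex
    pair absent from the current graph (rejection sampling), so the edge
    count is preserved exactly.  With ``k`` moves the structural Hamming
    distance to ``g`` is at most ``2k``.
    """
    if n_moves < 0:
        raise ValueError("n_moves must be non-negative")
    if n_moves > g.n_edges:
        raise ValueError(f"n_moves={n_moves} exceeds edge count {g.n_edges}")
    if n_moves == 0:
        return g
    max_edges = g.n_vertices * (g.n_vertices - 1) // 2
    if g.n_edges == max_edges:
        raise ValueError("cannot rewire a complete graph: no absent pair available")
    rng = np.random.default_rng(seed)
    edges = sorted(g.edges)
    current = set(edges)
    move_idx = rng.choice(len(edges), size=n_moves, replace=False)
    for idx in move_idx:
        old = edges[idx]
        current.discard(old)
        while True:
            i, j = rng.integers(0, g.n_vertices, size=2)
            if i == j:
                continue
            cand = _normalize_edge(int(i), int(j))
            if cand not in current:
                current.add(cand)
                break
    return Graph(g.n_vertices, frozenset(current), g.vertex_labels)


def structural_hamming_distance(g1: Graph, g2: Graph) -> int:
    """Number of edge slots in which two graphs on the same vertex set differ:
    ``|E1 ∪ E2| - |E1 ∩ E2|`` (size of the symmetric difference)."""
    if g1.n_vertices != g2.n_vertices:
        raise ValueError(
            f"vertex counts differ: {g1.n_vertices} != {g2.n_vertices}"
        )
    return len(g1.edges.symmetric_difference(g2.edges))


# ---------------------------------------------------------------------------
# File formats: two-column edge lists and square labelled adjacency matrices.
# ---------------------------------------------------------------------------

def read_edge_list(path, vertex_labels=None, sep: str | None = None) -> Graph:
    """Read a two-column delimited edge list of vertex labels.

    One edge per line, ``#`` starts a comment.  If ``vertex_labels`` is not
    given, the vertex set is the sorted set of labels seen in the file.
    """
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split(sep) if sep else line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {parts!r}")
            pairs.append((parts[0], parts[1]))
    if vertex_labels is None:
        vertex_labels = sorted({v for pair in pairs for v in pair})
    index = {lab: i for i, lab in enumerate(vertex_labels)}
    edges = set()
    for a, b in pairs:
        if a not in index or b not in index:
            missing = a if a not in index else b
            raise ValueError(f"edge endpoint {missing!r} not in vertex labels")
        edges.add(_normalize_edge(index[a], index[b]))
    return Graph(len(vertex_labels), frozenset(edges), tuple(vertex_labels))


def write_edge_list(g: Graph, path, sep: str = "\t") -> None:
    labels = g.vertex_labels or tuple(str(i) for i in range(g.n_vertices))
    with open(path, "w") as fh:
        fh.write("# edge list: one undirected edge per line\n")
        for i, j in sorted(g.edges):
            fh.write(f"{labels[i]}{sep}{labels[j]}\n")


def read_adjacency(path, sep: str = "\t", binarize: bool = False) -> Graph:
    """Read a square labelled adjacency matrix (header row and column).

    The matrix must be symmetric.  Entries other than 0/1 are rejected unless
    ``binarize=True`` (then any nonzero entry becomes an edge).
    """
    import pandas as pd

    df = pd.read_csv(path, sep=sep, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("adjacency matrix row and column labels differ")
    A = df.to_numpy(dtype=float)
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency matrix is not symmetric")
    if not binarize and not np.isin(A, (0.0, 1.0)).all():
        raise ValueError(
            "adjacency matrix has weighted entries; pass binarize=True to "
            "threshold nonzero entries to edges"
        )
    p = A.shape[0]
    edges = {
        _normalize_edge(i, j)
        for i in range(p)
        for j in range(i + 1, p)
        if A[i, j] != 0.0
    }
    return Graph(p, frozenset(edges), tuple(str(c) for c in df.columns))
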