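"""Graph containers, I/O and seeded generators.

The reconstruction pipeline treats a network as a labeled, undirected,
simple graph.  Node labels are strings (``"1"``, ``"2"``, ... in the
classical benchmarks); all numerical work uses the 0-based position of a
label in the graph's deterministic node order.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Graph",
    "read_edge_list",
    "write_edge_list",
    "read_adjacency_csv",
    "write_adjacency_csv",
    "karate_club",
    "generate_benchmark16",
    "generate_random",
    "graph_density",
]


class GraphFormatError(ValueError):
    """Raised for malformed graph files or invalid graph structure."""


class Graph:
    """Labeled undirected simple graph.

    Parameters
    ----------
    nodes
        Node labels in the order that defines matrix row/column positions.
    edges
        Iterable of label pairs.  Orientation and duplicates are ignored;
        self-loops are rejected (every matrix in the pipeline has a
        structurally zero diagonal).
    """

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]] = ()):
        self._nodes: list[str] = []
        self._index: dict[str, int] = {}
        for label in nodes:
            label = str(label)
            if label not in self._index:
                self._index[label] = len(self._nodes)
                self._nodes.append(label)
        self._edges: set[tuple[str, str]] = set()
        for u, v in edges:
            self.add_edge(str(u), str(v))

    # -- construction -------------------------------------------------

    def add_node(self, label: str) -> None:
        label = str(label)
        if label not in self._index:
            self._index[label] = len(self._nodes)
            self._nodes.append(label)

    def add_edge(self, u: str, v: str) -> None:
        u, v = str(u), str(v)
        if u == v:
            raise GraphFormatError(f"self-loop on node {u!r} not allowed")
        self.add_node(u)
        self.add_node(v)
        self._edges.add(self._canon(u, v))

    def _canon(self, u: str, v: str) -> tuple[str, str]:
        return (u, v) if self._index[u] < self._index[v] else (v, u)

    # -- queries -------------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self._nodes)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._edges)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def index_of(self, label: str) -> int:
        try:
            return self._index[str(label)]
        except KeyError:
            raise KeyError(f"unknown node label {label!r}") from None

    def has_edge(self, u: str, v: str) -> bool:
        u, v = str(u), str(v)
        if u not in self._index or v not in self._index or u == v:
            return False
        return self._canon(u, v) in self._edges

    def degree(self, label: str) -> int:
        label = str(label)
        self.index_of(label)
        return sum(1 for e in self._edges if label in e)

    def neighbors(self, label: str) -> list[str]:
        label = str(label)
        self.index_of(label)
        out = []
        for u, v in self._edges:
            if u == label:
                out.append(v)
            elif v == label:
                out.append(u)
        return sorted(out, key=self.index_of)

    def adjacency_matrix(self) -> np.ndarray:
        """Dense 0/1 adjacency in node order (symmetric, zero diagonal)."""
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=np.int64)
        for u, v in self._edges:
            i, j = self._index[u], self._index[v]
            a[i, j] = a[j, i] = 1
        return a

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from(self._edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Graph":
        return cls((str(n) for n in g.nodes()), ((str(u), str(v)) for u, v in g.edges()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return set(self._nodes) == set(other._nodes) and {
            frozenset(e) for e in self._edges
        } == {frozenset(e) for e in other._edges}

    def __repr__(self) -> str:  # pragma: no cover
        return f"Graph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def read_edge_list(path: str | Path) -> Graph:
    """Read a whitespace-delimited edge list.

    One edge per line (first two tokens are the endpoints); lines starting
    with ``#`` and blank lines are ignored.  Duplicate edges in either
    orientation collapse to one undirected edge.
    """
    g = Graph([])
    n_edges_seen = 0
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise GraphFormatError(f"{path}:{lineno}: expected two node labels, got {raw!r}")
        u, v = tokens[0], tokens[1]
        if u == v:
            raise GraphFormatError(f"{path}:{lineno}: self-loop {u!r} not allowed")
        g.add_edge(u, v)
        n_edges_seen += 1
    if n_edges_seen == 0:
        raise GraphFormatError(f"{path}: no edges")
    return g


def write_edge_list(g: Graph, path: str | Path) -> None:
    lines = [f"{u}\t{v}" for u, v in sorted(g.edges, key=lambda e: (g.index_of(e[0]), g.index_of(e[1])))]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_adjacency_csv(g: Graph, path: str | Path) -> None:
    """Write the labeled 0/1 adjacency matrix as CSV (labels on both axes)."""
    a = g.adjacency_matrix()
    df = pd.DataFrame(a, index=list(g.nodes), columns=list(g.nodes))
    df.to_csv(path)


def read_adjacency_csv(path: str | Path) -> Graph:
    """Read a labeled adjacency CSV back into a :class:`Graph`.

    The matrix must be binary, symmetric, zero-diagonal, with identical row
    and column labels.
    """
    df = pd.read_csv(path, index_col=0)
    labels = [str(c) for c in df.columns]
    row_labels = [str(r) for r in df.index]
    if labels != row_labels:
        raise GraphFormatError(f"{path}: row labels differ from column labels")
    a = df.to_numpy()
    if not np.isin(a, (0, 1)).all():
        raise GraphFormatError(f"{path}: adjacency entries must be 0 or 1")
    if np.diag(a).any():
        raise GraphFormatError(f"{path}: nonzero diagonal (self-loop)")
    if not np.array_equal(a, a.T):
        raise GraphFormatError(f"{path}: adjacency matrix is not symmetric")
    g = Graph(labels)
    for i, j in zip(*np.nonzero(np.triu(a))):
        g.add_edge(labels[i], labels[j])
    return g


# ---------------------------------------------------------------------------
# fixtures and generators
# ---------------------------------------------------------------------------

# Zachary's karate club: the canonical published 78-edge list, nodes 1..34.
_KARATE_EDGES = """\
1 2|1 3|1 4|1 5|1 6|1 7|1 8|1 9|1 11|1 12|1 13|1 14|1 18|1 20|1 22|1 32|\
2 3|2 4|2 8|2 14|2 18|2 20|2 22|2 31|3 4|3 8|3 9|3 10|3 14|3 28|3 29|3 33|\
4 8|4 13|4 14|5 7|5 11|6 7|6 11|6 17|7 17|9 31|9 33|9 34|10 34|14 34|15 33|\
15 34|16 33|16 34|19 33|19 34|20 34|21 33|21 34|23 33|23 34|24 26|24 28|\
24 30|24 33|24 34|25 26|25 28|25 32|26 32|27 30|27 34|28 34|29 32|29 34|\
30 33|30 34|31 33|31 34|32 33|32 34|33 34"""


def karate_club() -> Graph:
    """Zachary's karate club network: 34 nodes, 78 edges, density 0.139.

    The standard small social-network benchmark with two communities
    centered on nodes 1 and 34.
    """
    g = Graph([str(i) for i in range(1, 35)])
    for pair in _KARATE_EDGES.split("|"):
        u, v = pair.split()
        g.add_edge(u, v)
    return g


def generate_benchmark16(rng_seed: int) -> Graph:
    """Connected 16-node, 39-edge test network, deterministic per seed.

    Samples a uniform 39-edge subset of the complete graph on 16 nodes and
    re-samples until the result is connected.
    """
    rng = np.random.default_rng(rng_seed)
    n, m = 16, 39
    labels = [str(i) for i in range(1, n + 1)]
    all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    while True:
        chosen = rng.choice(len(all_pairs), size=m, replace=False)
        g = Graph(labels)
        for k in chosen:
            i, j = all_pairs[k]
            g.add_edge(labels[i], labels[j])
        if nx.is_connected(g.to_networkx()):
            return g


def generate_random(family: str, params: Mapping[str, object], rng_seed: int) -> Graph:
    """Seeded synthetic graph generator.

    Families: ``er`` (Erdos-Renyi G(n, p)), ``ba`` (Barabasi-Albert with
    ``n`` nodes and ``m`` attachments per new node), ``star`` (hub = node
    "1"), ``path`` (chain 1-2-...-n).  Labels are "1".."n".
    """
    params = dict(params)
    if family == "er":
        n, p = int(params["n"]), float(params["p"])
        if n < 1 or not 0.0 <= p <= 1.0:
            raise ValueError(f"invalid er params n={n}, p={p}")
        nxg = nx.gnp_random_graph(n, p, seed=int(rng_seed))
    elif family == "ba":
        n, m = int(params["n"]), int(params["m"])
        if n < 2 or not 1 <= m < n:
            raise ValueError(f"invalid ba params n={n}, m={m}")
        nxg = nx.barabasi_albert_graph(n, m, seed=int(rng_seed))
    elif family == "star":
        n = int(params["n"])
        if n < 1:
            raise ValueError(f"invalid star size n={n}")
        nxg = nx.star_graph(n - 1)
    elif family == "path":
        n = int(params["n"])
        if n < 1:
            raise ValueError(f"invalid path size n={n}")
        nxg = nx.path_graph(n)
    else:
        raise ValueError(f"unknown graph family {family!r}")
    mapping = {i: str(i + 1) for i in nxg.nodes()}
    g = Graph([mapping[i] for i in sorted(nxg.nodes())])
    for u, v in nxg.edges():
        g.add_edge(mapping[u], mapping[v])
    return g


def graph_density(g: Graph) -> float:
    """Density 2E / (N (N - 1)) of an undirected simple graph."""
    n = g.n_nodes
    if n < 2:
        raise ValueError("density requires at least 2 nodes")
    return 2.0 * g.n_edges / (n * (n - 1))
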