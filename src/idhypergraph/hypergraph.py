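"""Hypergraph data structure: incidence matrix, weights, and degree operators.

Vertices are 0-based integers internally; all text formats and reports use
1-based IDs. Hyperedges are stored as sorted tuples of unique vertex indices
with a nonnegative real weight and a positive integer multiplicity each
(multiplicities arise from merging duplicated hyperedges).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from ._errors import InvalidInputError

__all__ = [
    "Hypergraph",
    "DegreeProfile",
    "build_incidence",
    "degrees",
    "merge_duplicates",
    "read_hypergraph",
    "write_hypergraph",
]


@dataclass
class Hypergraph:
    """A weighted hypergraph ``G = (V, E, w)`` with edge multiplicities.

    Parameters
    ----------
    n_vertices
        Number of vertices ``N``; vertex indices run over ``0..N-1``.
    hyperedges
        Ordered list of hyperedges, each a sorted tuple of distinct vertex
        indices. Every hyperedge must be a nonempty subset of the vertex set.
    weights
        Per-hyperedge nonnegative weight ``w(e_j)``; defaults to 1 for every
        hyperedge (identity weight matrix).
    multiplicities
        Per-hyperedge positive integer count ``a_j``; defaults to 1.
    vertex_labels
        Optional subject IDs, one per vertex.
    """

    n_vertices: int
    hyperedges: list[tuple[int, ...]]
    weights: np.ndarray = None  # type: ignore[assignment]
    multiplicities: np.ndarray = None  # type: ignore[assignment]
    vertex_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_vertices < 0:
            raise InvalidInputError("n_vertices must be nonnegative")
        canon = []
        for j, e in enumerate(self.hyperedges):
            members = tuple(sorted(set(int(v) for v in e)))
            if not members:
                raise InvalidInputError(f"hyperedge {j} is empty")
            if members[0] < 0 or members[-1] >= self.n_vertices:
                raise InvalidInputError(
                    f"hyperedge {j} has vertex index outside 0..{self.n_vertices - 1}: {e}"
                )
            canon.append(members)
        self.hyperedges = canon
        m = len(self.hyperedges)
        if self.weights is None:
            self.weights = np.ones(m)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (m,):
                raise InvalidInputError("weights length must match hyperedge count")
            if np.any(self.weights < 0) or not np.all(np.isfinite(self.weights)):
                raise InvalidInputError("weights must be finite and nonnegative")
        if self.multiplicities is None:
            self.multiplicities = np.ones(m, dtype=int)
        else:
            self.multiplicities = np.asarray(self.multiplicities, dtype=int)
            if self.multiplicities.shape != (m,):
                raise InvalidInputError("multiplicities length must match hyperedge count")
            if np.any(self.multiplicities < 1):
                raise InvalidInputError("multiplicities must be positive integers")
        if self.vertex_labels is not None and len(self.vertex_labels) != self.n_vertices:
            raise InvalidInputError("vertex_labels length must equal n_vertices")

    @property
    def n_hyperedges(self) -> int:
        return len(self.hyperedges)

    def incidence(self) -> sp.csr_matrix:
        """Binary |V| x |E| incidence matrix with H[v, e] = 1 iff v in e."""
        rows, cols = [], []
        for j, e in enumerate(self.hyperedges):
            rows.extend(e)
            cols.extend([j] * len(e))
        data = np.ones(len(rows), dtype=np.int8)
        return sp.csr_matrix(
            (data, (rows, cols)), shape=(self.n_vertices, self.n_hyperedges)
        )

    def incidence_dense(self) -> np.ndarray:
        return self.incidence().toarray()


@dataclass(frozen=True)
class DegreeProfile:
    """Vertex degrees d(v), hyperedge degrees delta(e), and max edge size."""

    vertex_degrees: np.ndarray
    hyperedge_degrees: np.ndarray
    max_edge_size: int = field(default=0)

    @property
    def total_volume(self) -> float:
        return float(self.vertex_degrees.sum())


def build_incidence(
    hyperedges: Iterable[Iterable[int]],
    n_vertices: int,
    weights: Sequence[float] | None = None,
    vertex_labels: list[str] | None = None,
) -> Hypergraph:
    """Assemble a :class:`Hypergraph` from raw vertex subsets.

    Weights default to 1 for every hyperedge (identity weight matrix).
    Out-of-range vertex indices and empty hyperedges raise
    :class:`InvalidInputError`.
    """
    edges = [tuple(e) for e in hyperedges]
    w = None if weights is None else np.asarray(list(weights), dtype=float)
    return Hypergraph(
        n_vertices=n_vertices, hyperedges=edges, weights=w, vertex_labels=vertex_labels
    )


def degrees(G: Hypergraph) -> DegreeProfile:
    """Degree profile of ``G``.

    ``d(v_i) = sum_j w(e_j) * a_j * H[i, j]`` and ``delta(e_j) = |e_j|``;
    ``max_edge_size`` is the largest hyperedge cardinality (0 when there are
    no hyperedges).
    """
    d = np.zeros(G.n_vertices)
    sizes = np.zeros(G.n_hyperedges, dtype=int)
    for j, e in enumerate(G.hyperedges):
        sizes[j] = len(e)
        contrib = G.weights[j] * G.multiplicities[j]
        for v in e:
            d[v] += contrib
    kbar = int(sizes.max()) if len(sizes) else 0
    return DegreeProfile(vertex_degrees=d, hyperedge_degrees=sizes, max_edge_size=kbar)


def merge_duplicates(G: Hypergraph) -> Hypergraph:
    """Collapse hyperedges with identical vertex sets into one edge.

    Multiplicities are summed weighted by relative edge weight so that the
    degree profile is preserved exactly. With unit weights this is a plain
    multiplicity sum. Edge order follows first occurrence.
    """
    order: dict[tuple[int, ...], int] = {}
    weights: list[float] = []
    mults: list[int] = []
    mass: list[float] = []  # accumulated w*a per unique edge
    for j, e in enumerate(G.hyperedges):
        if e in order:
            idx = order[e]
            mults[idx] += int(G.multiplicities[j])
            mass[idx] += float(G.weights[j] * G.multiplicities[j])
        else:
            order[e] = len(weights)
            weights.append(float(G.weights[j]))
            mults.append(int(G.multiplicities[j]))
            mass.append(float(G.weights[j] * G.multiplicities[j]))
    # recompute weight = mass / multiplicity so w*a (degree contribution)
    # is conserved even when duplicate edges carried distinct weights
    new_weights = np.array([m / a for m, a in zip(mass, mults)])
    return Hypergraph(
        n_vertices=G.n_vertices,
        hyperedges=list(order.keys()),
        weights=new_weights,
        multiplicities=np.array(mults, dtype=int),
        vertex_labels=G.vertex_labels,
    )


def write_hypergraph(G: Hypergraph, path) -> None:
    """Write the edge-list text format.

    One line per hyperedge: whitespace-separated 1-based vertex IDs, then
    optional ``w=<float>`` and ``a=<int>`` tokens (omitted when 1). A header
    comment records the vertex count so empty vertices survive round-trips.
    """
    with open(path, "w") as fh:
        fh.write(f"# n_vertices={G.n_vertices}\n")
        if G.vertex_labels is not None:
            fh.write("# labels=" + ",".join(G.vertex_labels) + "\n")
        for j, e in enumerate(G.hyperedges):
            parts = [str(v + 1) for v in e]
            if G.weights[j] != 1.0:
                parts.append(f"w={float(G.weights[j])!r}")
            if G.multiplicities[j] != 1:
                parts.append(f"a={int(G.multiplicities[j])}")
            fh.write(" ".join(parts) + "\n")


def read_hypergraph(path) -> Hypergraph:
    """Parse the edge-list text format written by :func:`write_hypergraph`."""
    edges: list[tuple[int, ...]] = []
    weights: list[float] = []
    mults: list[int] = []
    n_vertices = -1
    labels: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("n_vertices="):
                    n_vertices = int(body.split("=", 1)[1])
                elif body.startswith("labels="):
                    labels = body.split("=", 1)[1].split(",")
                continue
            w, a = 1.0, 1
            members = []
            for tok in line.split():
                if tok.startswith("w="):
                    w = float(tok[2:])
                elif tok.startswith("a="):
                    a = int(tok[2:])
                else:
                    members.append(int(tok) - 1)
            edges.append(tuple(members))
            weights.append(w)
            mults.append(a)
    if n_vertices < 0:
        n_vertices = 1 + max((max(e) for e in edges if e), default=-1)
    return Hypergraph(
        n_vertices=n_vertices,
        hyperedges=edges,
        weights=np.array(weights),
        multiplicities=np.array(mults, dtype=int),
        vertex_labels=labels,
    )
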