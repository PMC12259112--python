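"""Graph and label data structures for connectome-style edge lists.

A connectome is modelled as a directed weighted graph: nodes are neurons,
edges synaptic connections, and the edge weight the number of synapses per
connection.  Input tables commonly list one row per connection (or per
synapse); duplicate (source, target) rows are therefore summed at load.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger("conntype")

__all__ = [
    "WeightedDigraph",
    "Labeling",
    "read_edge_list",
    "read_labels",
    "write_assignments",
    "GraphFormatError",
]


class GraphFormatError(ValueError):
    """Raised for malformed or contract-violating input tables."""


class WeightedDigraph:
    """Directed weighted graph with first-appearance node ordering.

    Parallel edge records are collapsed (weights summed) and zero-weight
    records dropped, so every stored weight is strictly positive.
    Self-loops are permitted.  Node identifiers are opaque strings; the
    order in which they first appear is the canonical order used for all
    deterministic tie-breaking downstream.
    """

    def __init__(self, nodes: Sequence[str], adjacency: sp.spmatrix):
        self.nodes: list[str] = list(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise GraphFormatError("duplicate node identifiers")
        self._index: dict[str, int] = {u: i for i, u in enumerate(self.nodes)}
        adj = sp.csr_matrix(adjacency, dtype=np.float64)
        if adj.shape != (len(self.nodes), len(self.nodes)):
            raise GraphFormatError("adjacency shape does not match node count")
        adj.eliminate_zeros()
        if adj.nnz and adj.data.min() < 0:
            raise GraphFormatError("negative edge weight")
        self._adj = adj
        self._adj_t = adj.T.tocsr()

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        extra_nodes: Iterable[str] = (),
    ) -> "WeightedDigraph":
        """Build a graph from (source, target, weight) records.

        Duplicate (source, target) pairs are summed; node order is
        first-appearance order over the edge stream, followed by any
        isolated ``extra_nodes``.
        """
        order: dict[str, int] = {}
        rows, cols, vals = [], [], []
        for src, tgt, w in edges:
            w = float(w)
            if w < 0:
                raise GraphFormatError(
                    f"negative weight {w!r} on edge ({src!r}, {tgt!r})"
                )
            for u in (src, tgt):
                if u not in order:
                    order[u] = len(order)
            rows.append(order[src])
            cols.append(order[tgt])
            vals.append(w)
        for u in extra_nodes:
            if u not in order:
                order[u] = len(order)
        n = len(order)
        adj = sp.coo_matrix(
            (vals, (rows, cols)), shape=(n, n), dtype=np.float64
        ).tocsr()  # COO->CSR sums duplicates
        return cls(list(order), adj)

    # -- basic queries -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        return int(self._adj.nnz)

    @property
    def total_weight(self) -> float:
        return float(self._adj.sum())

    @property
    def adjacency(self) -> sp.csr_matrix:
        """n x n CSR matrix; entry (i, j) = weight of edge i -> j."""
        return self._adj

    @property
    def adjacency_t(self) -> sp.csr_matrix:
        return self._adj_t

    def index(self, node: str) -> int:
        return self._index[node]

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def out_strengths(self) -> np.ndarray:
        return np.asarray(self._adj.sum(axis=1)).ravel()

    def in_strengths(self) -> np.ndarray:
        return np.asarray(self._adj.sum(axis=0)).ravel()

    def weight(self, src: str, tgt: str) -> float:
        return float(self._adj[self._index[src], self._index[tgt]])

    def e(self, sources: Iterable[str], targets: Iterable[str]) -> float:
        """Total edge weight e(A, B) from node set A to node set B."""
        rows = [self._index[u] for u in sources]
        cols = [self._index[v] for v in targets]
        return float(self._adj[np.ix_(rows, cols)].sum())

    def e_out(self, node: str, targets: Iterable[str]) -> float:
        return self.e([node], targets)

    def e_in(self, sources: Iterable[str], node: str) -> float:
        return self.e(sources, [node])

    def with_nodes(self, extra: Iterable[str]) -> "WeightedDigraph":
        """Return a graph extended with isolated nodes (appended in order)."""
        new = [u for u in extra if u not in self._index]
        if not new:
            return self
        n = self.n + len(new)
        adj = sp.csr_matrix(
            (self._adj.data, self._adj.indices, self._adj.indptr),
            shape=(self.n, self.n),
        )
        adj.resize((n, n))
        return WeightedDigraph(self.nodes + new, adj)

    def edge_records(self) -> list[tuple[str, str, float]]:
        coo = self._adj.tocoo()
        return [
            (self.nodes[i], self.nodes[j], float(w))
            for i, j, w in zip(coo.row, coo.col, coo.data)
        ]


@dataclass(frozen=True)
class Labeling:
    """A (possibly partial) assignment of nodes to type labels.

    When total over a graph, the preimages of ``label_universe`` form the
    partition C1..Ck; ``seed_set`` marks nodes whose labels are fixed
    inputs (semi-supervised mode).
    """

    assignment: Mapping[str, str]
    seed_set: frozenset[str] = field(default_factory=frozenset)
    label_universe: tuple[str, ...] = ()

    def __post_init__(self):
        universe = self.label_universe or tuple(
            sorted(set(self.assignment.values()))
        )
        object.__setattr__(self, "label_universe", tuple(universe))
        object.__setattr__(self, "assignment", dict(self.assignment))
        object.__setattr__(self, "seed_set", frozenset(self.seed_set))
        missing = self.seed_set - self.assignment.keys()
        if missing:
            raise GraphFormatError(
                f"seeds without labels: {sorted(missing)[:5]}"
            )
        extra = set(self.assignment.values()) - set(self.label_universe)
        if extra:
            raise GraphFormatError(
                f"labels outside the declared universe: {sorted(extra)[:5]}"
            )
        if not self.label_universe:
            raise GraphFormatError("empty label universe")

    @property
    def k(self) -> int:
        return len(self.label_universe)

    def is_total(self, graph: WeightedDigraph) -> bool:
        return all(u in self.assignment for u in graph.nodes)

    def label_indices(self, graph: WeightedDigraph) -> np.ndarray:
        """Label index per node, in graph node order. Requires totality."""
        lut = {lab: i for i, lab in enumerate(self.label_universe)}
        try:
            return np.array(
                [lut[self.assignment[u]] for u in graph.nodes], dtype=np.intp
            )
        except KeyError as exc:
            raise GraphFormatError(f"node without label: {exc}") from exc

    def clusters(self, graph: WeightedDigraph) -> list[np.ndarray]:
        """Member node-index arrays per label, in label_universe order."""
        idx = self.label_indices(graph)
        return [np.flatnonzero(idx == j) for j in range(self.k)]

    @classmethod
    def from_indices(
        cls,
        graph: WeightedDigraph,
        indices: np.ndarray,
        labels: Sequence[str],
        seed_set: Iterable[str] = (),
    ) -> "Labeling":
        assignment = {
            u: labels[j] for u, j in zip(graph.nodes, np.asarray(indices))
        }
        return cls(assignment, frozenset(seed_set), tuple(labels))


# -- file I/O ----------------------------------------------------------

_DELIMS = {"tsv": "\t", "csv": ","}


def _sniff_delimiter(path: str) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_edge_list(
    path: str,
    dialect: str | None = None,
    has_header: bool | None = None,
) -> WeightedDigraph:
    """Read a 3-column (source, target, weight) table into a graph.

    ``dialect`` is ``"tsv"`` or ``"csv"``; when None it is sniffed from the
    first line.  ``has_header=None`` treats the first row as a header iff
    its weight column does not parse as a number.
    """
    delim = _DELIMS[dialect] if dialect else _sniff_delimiter(path)
    edges: list[tuple[str, str, float]] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 3 columns, got {len(row)}"
                )
            src, tgt, w_raw = (c.strip() for c in row)
            if lineno == 1:
                try:
                    float(w_raw)
                    numeric = True
                except ValueError:
                    numeric = False
                if has_header is True or (has_header is None and not numeric):
                    continue
            try:
                w = float(w_raw)
            except ValueError as exc:
                raise GraphFormatError(
                    f"{path}:{lineno}: unparseable weight {w_raw!r}"
                ) from exc
            if w < 0:
                raise GraphFormatError(
                    f"{path}:{lineno}: negative weight {w}"
                )
            edges.append((src, tgt, w))
    graph = WeightedDigraph.from_edges(edges)
    logger.info(
        "loaded %s: n=%d, m=%d, total weight=%g",
        path, graph.n, graph.m, graph.total_weight,
    )
    return graph


def write_edge_list(graph: WeightedDigraph, path: str, dialect: str = "tsv") -> None:
    delim = _DELIMS[dialect]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        for src, tgt, w in graph.edge_records():
            writer.writerow([src, tgt, f"{w:g}"])


def read_labels(path: str) -> Labeling:
    """Read a 2-column (node, label) CSV into a partial Labeling.

    All listed nodes become seeds; the label universe is the sorted set of
    distinct labels.  Duplicate rows are accepted when consistent and
    rejected when conflicting.
    """
    assignment: dict[str, str] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 2 columns, got {len(row)}"
                )
            node, label = row[0].strip(), row[1].strip()
            if lineno == 1 and (node.lower(), label.lower()) == ("node", "label"):
                continue
            if node in assignment and assignment[node] != label:
                raise GraphFormatError(
                    f"{path}:{lineno}: conflicting labels for node {node!r}: "
                    f"{assignment[node]!r} vs {label!r}"
                )
            assignment[node] = label
    if not assignment:
        raise GraphFormatError(f"{path}: empty label table")
    return Labeling(assignment, seed_set=frozenset(assignment))


def reconcile_labels(
    graph: WeightedDigraph, labeling: Labeling, strict: bool = False
) -> tuple[WeightedDigraph, Labeling]:
    """Handle labeled nodes absent from the graph.

    Lenient mode (default) logs a warning and retains them as isolated
    nodes; strict mode raises.
    """
    absent = [u for u in labeling.assignment if u not in graph]
    if absent:
        if strict:
            raise GraphFormatError(
                f"{len(absent)} labeled nodes absent from graph "
                f"(first: {absent[:5]})"
            )
        logger.warning(
            "%d labeled nodes absent from graph; kept as isolated nodes",
            len(absent),
        )
        graph = graph.with_nodes(absent)
    return graph, labeling


def write_assignments(
    labeling: Labeling,
    path: str,
    ranked: Mapping[str, Sequence[tuple[str, float]]] | None = None,
) -> None:
    """Write node,label rows, optionally with ranked alternatives.

    With ``ranked``, each row gains rank_i_label,rank_i_distance column
    pairs; distances are non-decreasing within a row by construction of
    the ranking.
    """
    depth = max((len(v) for v in ranked.values()), default=0) if ranked else 0
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        header = ["node", "label"]
        for i in range(1, depth + 1):
            header += [f"rank{i}_label", f"rank{i}_distance"]
        writer.writerow(header)
        for node in labeling.assignment:
            row: list[str] = [node, labeling.assignment[node]]
            if ranked is not None:
                for lab, dist in ranked.get(node, []):
                    row += [lab, f"{dist:.12g}"]
            writer.writerow(row)
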