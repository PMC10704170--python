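"""Parsing of SIF interaction tables and construction of simple undirected graphs.

The SIF dialect accepted here is tab-separated with at least three columns
(participant A, interaction type, participant B); extra columns of extended
SIF exports are ignored.  Graphs are simplified: parallel edges are collapsed
to a single undirected edge and self-loops are dropped (both counted), and
node order is lexicographic so every derived matrix is reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Interaction types retained by default when building the graph.
DEFAULT_INTERACTION_TYPES = frozenset(
    {
        "interacts-with",
        "in-complex-with",
        "catalysis-precedes",
        "controls-state-change-of",
        "controls-transport-of",
        "controls-transport-of-chemical",
        "controls-expression-of",
        "controls-phosphorylation-of",
        "controls-production-of",
        "chemical-affects",
        "consumption-controlled-by",
    }
)


class SifParseError(ValueError):
    """Raised when a SIF file cannot be parsed."""


@dataclass
class InteractionTable:
    """Raw rows of a SIF file: (participant_a, interaction_type, participant_b)."""

    rows: list[tuple[str, str, str]]
    source_path: str = "<memory>"

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.rows)


@dataclass(frozen=True)
class GeneNetwork:
    """Simple undirected graph with deterministic (lexicographic) node order.

    ``edges`` holds unordered node-index pairs stored as ``(i, j)`` with
    ``i < j``, sorted.  ``multi_edge_count`` is the number of non-self-loop
    input rows before collapsing parallel edges; ``self_loop_count`` the
    number of dropped self-loop rows.
    """

    node_ids: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]
    multi_edge_count: int = 0
    self_loop_count: int = 0

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index(self, node_id: str) -> int:
        try:
            return self.node_ids.index(node_id)
        except ValueError as exc:  # pragma: no cover - defensive
            raise KeyError(node_id) from exc

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=float)
        for i, j in self.edges:
            deg[i] += 1.0
            deg[j] += 1.0
        return deg

    def adjacency_matrix(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=float)
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a

    def edge_node_ids(self) -> list[tuple[str, str]]:
        return [(self.node_ids[i], self.node_ids[j]) for i, j in self.edges]


def parse_sif(path: str | Path) -> InteractionTable:
    """Parse a SIF file into an :class:`InteractionTable`.

    Blank lines are skipped; lines with fewer than three tab-separated,
    non-empty fields raise :class:`SifParseError` naming the line number.
    Columns beyond the third are dropped.
    """
    path = Path(path)
    rows: list[tuple[str, str, str]] = []
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3 or any(not f.strip() for f in fields[:3]):
                raise SifParseError(
                    f"{path}: line {lineno}: expected >= 3 non-empty "
                    f"tab-separated fields, got {fields[:3]!r}"
                )
            rows.append((fields[0], fields[1], fields[2]))
    if not rows:
        raise SifParseError(f"{path}: empty SIF file")
    return InteractionTable(rows=rows, source_path=str(path))


def build_graph(
    table: InteractionTable,
    allowed_types: Iterable[str] | None = None,
) -> GeneNetwork:
    """Build the simplified undirected graph from an interaction table.

    Rows whose interaction type is not in ``allowed_types`` are excluded.
    Parallel edges are collapsed (the pre-collapse count is recorded in
    ``multi_edge_count``) and self-loops dropped and counted.
    """
    if allowed_types is None:
        allowed = DEFAULT_INTERACTION_TYPES
    else:
        allowed = frozenset(allowed_types)
    if not allowed:
        raise ValueError("allowed_types must be non-empty")

    surviving = [row for row in table.rows if row[1] in allowed]
    if not surviving:
        raise ValueError(
            "no rows survived interaction-type filtering; "
            f"allowed types: {sorted(allowed)}"
        )

    names: set[str] = set()
    for a, _, b in surviving:
        names.add(a)
        names.add(b)
    node_ids = tuple(sorted(names))
    idx = {name: i for i, name in enumerate(node_ids)}

    self_loops = 0
    multi = 0
    edge_set: set[tuple[int, int]] = set()
    for a, _, b in surviving:
        if a == b:
            self_loops += 1
            continue
        multi += 1
        i, j = idx[a], idx[b]
        edge_set.add((min(i, j), max(i, j)))
    if not edge_set:
        raise ValueError("graph has zero edges after simplification")

    return GeneNetwork(
        node_ids=node_ids,
        edges=tuple(sorted(edge_set)),
        multi_edge_count=multi,
        self_loop_count=self_loops,
    )


def network_from_edges(edges: Iterable[tuple[str, str]]) -> GeneNetwork:
    """Build a :class:`GeneNetwork` directly from string edge pairs."""
    rows = [(a, "interacts-with", b) for a, b in edges]
    return build_graph(InteractionTable(rows=rows))


def node_masses(g: GeneNetwork) -> np.ndarray:
    """Node masses = total degree in the simplified graph.

    Isolated nodes get mass 0 and a warning; they must be excluded before
    the spring model.
    """
    masses = g.degrees()
    n_isolated = int(np.sum(masses == 0))
    if n_isolated:
        logger.warning(
            "%d isolated node(s) assigned mass 0; exclude them from the "
            "spring model",
            n_isolated,
        )
    return masses


def oriented_incidence(g: GeneNetwork) -> np.ndarray:
    """Oriented node-by-edge incidence matrix, lexicographic orientation.

    For edge ``(i, j)`` with ``i < j`` the tail ``i`` gets +1 and the head
    ``j`` gets -1; columns follow the sorted edge order.
    """
    a = np.zeros((g.n_nodes, g.n_edges), dtype=float)
    for e, (i, j) in enumerate(g.edges):
        a[i, e] = 1.0
        a[j, e] = -1.0
    return a


def write_sif(
    g: GeneNetwork, path: str | Path, interaction_type: str = "interacts-with"
) -> None:
    """Write the simplified graph back to SIF with a single placeholder type."""
    with open(path, "w", encoding="utf-8") as handle:
        for a, b in g.edge_node_ids():
            handle.write(f"{a}\t{interaction_type}\t{b}\n")


def write_edge_list(g: GeneNetwork, path: str | Path) -> None:
    """Write the edge list as CSV (node_a,node_b)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("node_a,node_b\n")
        for a, b in g.edge_node_ids():
            handle.write(f"{a},{b}\n")


def write_node_table(g: GeneNetwork, path: str | Path) -> None:
    """Write the node table as CSV (node_id,degree)."""
    deg = g.degrees()
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("node_id,degree\n")
        for name, d in zip(g.node_ids, deg):
            handle.write(f"{name},{int(d)}\n")
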