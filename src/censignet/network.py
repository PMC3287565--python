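"""Protein interaction networks: ingest, merge, and context-constrained induction.

Interactions are treated as an unweighted, undirected simple graph over gene
symbols.  The *context-constrained* network is the subgraph of the complete
interactome induced by a gene set of interest (here: genes supported by at
least two signatures).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)


class EdgeListParseError(ValueError):
    """Raised for an interaction row without two endpoint symbols."""


@dataclass
class InteractionNetwork:
    """Simple undirected graph of gene symbols, backed by ``networkx.Graph``.

    Invariant: no self-loops, no parallel edges.  Constructors in this
    module guarantee it; ``assert_simple`` re-checks after any manipulation.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    name: str = ""

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def assert_simple(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise AssertionError(f"self-loops present: {loops[:3]}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    n_components: int
    n_isolated: int
    density: float


def _build_simple(
    nodes: Iterable[str], edge_rows: Iterable[tuple[str, str]], name: str
) -> tuple[InteractionNetwork, int, int]:
    """Assemble a simple graph, counting dropped self-rows and duplicates."""
    g = nx.Graph(name=name)
    g.add_nodes_from(nodes)
    n_self = 0
    n_dup = 0
    for u, v in edge_rows:
        if u == v:
            n_self += 1
            g.add_node(u)
            continue
        if g.has_edge(u, v):
            n_dup += 1
        g.add_edge(u, v)
    return InteractionNetwork(graph=g, name=name), n_self, n_dup


def read_edge_list(
    path: str | Path,
    fmt: str | None = None,
    header: bool = False,
    name: str | None = None,
) -> InteractionNetwork:
    """Read an interaction network from a 2-column TSV or a SIF file.

    TSV rows use columns 1-2 as endpoints (extra columns such as evidence
    codes are ignored); SIF rows are ``node relation node [node...]``, one
    edge per trailing node.  ``fmt`` is ``"tsv"`` or ``"sif"``; by default it
    is inferred from the file suffix.  Symbols are uppercased and stripped;
    self-rows and duplicate rows are collapsed with logged counts.
    """
    path = Path(path)
    if fmt is None:
        fmt = "sif" if path.suffix.lower() == ".sif" else "tsv"
    if fmt not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list format {fmt!r}")
    rows: list[tuple[str, str]] = []
    nodes: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#node"):
                fields = line.split("\t")
                if len(fields) >= 2 and fields[1].strip():
                    nodes.append(fields[1].strip().upper())
                continue
            if not line or line.startswith("#"):
                continue
            if header and lineno == 1:
                continue
            if fmt == "sif":
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) == 1:
                    # a lone node is legal SIF: an isolated node
                    nodes.append(fields[0].strip().upper())
                    continue
                if len(fields) < 3:
                    raise EdgeListParseError(
                        f"{path}:{lineno}: SIF row needs 'node relation node'"
                    )
                src = fields[0].strip().upper()
                for tgt in fields[2:]:
                    rows.append((src, tgt.strip().upper()))
            else:
                fields = line.split("\t")
                if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                    raise EdgeListParseError(
                        f"{path}:{lineno}: need two endpoint columns"
                    )
                rows.append((fields[0].strip().upper(), fields[1].strip().upper()))
    net, n_self, n_dup = _build_simple(nodes, rows, name or path.stem)
    logger.info(
        "read %s: %d nodes, %d edges (%d self-rows dropped, %d duplicate rows collapsed)",
        path, net.n_nodes, net.n_edges, n_self, n_dup,
    )
    return net


def write_edge_list(net: InteractionNetwork, path: str | Path) -> None:
    """Write the network as a sorted 2-column TSV (isolated nodes as a
    trailing ``#node`` comment block) for reproducible diffs."""
    path = Path(path)
    edges = sorted(tuple(sorted(e)) for e in net.edges)
    isolated = sorted(n for n in net.nodes if net.graph.degree(n) == 0)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")
        for n in isolated:
            fh.write(f"#node\t{n}\n")


def merge_networks(nets: Sequence[InteractionNetwork], name: str = "merged") -> InteractionNetwork:
    """Union of node sets and edge sets across sources; result is simple.

    Edge identity is the unordered symbol pair, so the same interaction
    reported by several databases is counted once.
    """
    if not nets:
        raise ValueError("merge_networks needs at least one network")
    g = nx.Graph(name=name)
    for net in nets:
        g.add_nodes_from(net.graph.nodes)
        g.add_edges_from(net.graph.edges)
    merged = InteractionNetwork(graph=g, name=name)
    merged.assert_simple()
    return merged


def induce_context_network(
    pin: InteractionNetwork,
    genes: Iterable[str],
    keep_isolated: bool = True,
    name: str = "context",
) -> InteractionNetwork:
    """Induce the subgraph of ``pin`` on ``genes`` (the context-constrained net).

    Genes absent from the interactome are dropped (count logged).  Projected
    genes with no retained interaction are kept as isolated nodes by default
    so that every filtered gene receives a centrality score; pass
    ``keep_isolated=False`` for the stricter connected-only reading.
    """
    genes = {g.strip().upper() for g in genes}
    present = genes & set(pin.graph.nodes)
    dropped = len(genes) - len(present)
    if dropped:
        logger.info("context induction: %d genes absent from the interactome", dropped)
    if not present:
        logger.warning("context induction: no query gene found in the interactome")
        return InteractionNetwork(graph=nx.Graph(), name=name)
    sub = nx.Graph(pin.graph.subgraph(present))
    if not keep_isolated:
        sub.remove_nodes_from([n for n, d in sub.degree() if d == 0])
    out = InteractionNetwork(graph=sub, name=name)
    out.assert_simple()
    return out


def network_summary(net: InteractionNetwork) -> NetworkSummary:
    """Node/edge/component counts, isolated-node count and edge density."""
    n = net.n_nodes
    m = net.n_edges
    density = 2.0 * m / (n * (n - 1)) if n >= 2 else 0.0
    n_components = nx.number_connected_components(net.graph) if n else 0
    n_isolated = sum(1 for _, d in net.graph.degree() if d == 0)
    return NetworkSummary(
        n_nodes=n,
        n_edges=m,
        n_components=n_components,
        n_isolated=n_isolated,
        density=density,
    )
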