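"""Six graph centralities for ranking genes in a constrained interactome.

For an undirected simple graph G(V, E) with adjacency matrix A:

* **DC** — degree centrality: the raw degree ``Deg(i)``.
* **BC** — betweenness: sum over unordered node pairs {s, t} (s != t != i)
  of the fraction of shortest s-t paths passing through i.
* **CC** — closeness: reciprocal of the sum of shortest-path lengths from i
  to every node reachable from i (component-restricted; a harmonic variant
  sums reciprocals of distances instead and handles disconnection natively).
* **SC** — subgraph centrality: the i-th diagonal entry of exp(A), i.e. the
  factorially damped count of closed walks at i, computed from the symmetric
  eigendecomposition A = V diag(w) V^T as ``sum_k V[i,k]^2 * exp(w_k)``.
* **EC** — eigenvector centrality: the i-th component of the principal
  eigenvector of A (entrywise absolute value, unit Euclidean norm).
* **IC** — information centrality (Stephenson-Zelen): on each connected
  component of size m >= 2, invert B = D - A + J to get R = (r_ij); the
  pairwise information is I_ij = (r_ii + r_jj - 2 r_ij)^-1 and
  ``IC(i) = m / sum_{j != i} (1 / I_ij)``.

All measures assign a score to every node, including isolated ones (degree
0, closeness 0, subgraph 1, information 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import shortest_path

logger = logging.getLogger(__name__)

from censignet.network import InteractionNetwork

#: Canonical measure order used across outputs.
MEASURES = ("DC", "BC", "CC", "SC", "EC", "IC")

# above this size the full symmetric eigendecomposition is replaced by a
# Lanczos solve for the measures that only need the principal pair
_DENSE_EIG_LIMIT = 2500


@dataclass
class CentralityScores:
    measure: str
    score: dict[str, float]
    network_name: str = ""

    def __getitem__(self, gene: str) -> float:
        return self.score[gene]


@dataclass
class RankedSignature:
    """Top-k gene list for one centrality measure, scores non-increasing."""

    measure: str
    genes: list[str]
    k: int


def _node_order(net: InteractionNetwork) -> list[str]:
    return sorted(net.graph.nodes)

def _adjacency(net: InteractionNetwork, order: Sequence[str]) -> sp.csr_array:
    return nx.to_scipy_sparse_array(net.graph, nodelist=list(order), format="csr", dtype=float)


def degree_centrality(net: InteractionNetwork) -> CentralityScores:
    """DC(i) = Deg(i): raw (unnormalized) degree."""
    score = {n: float(d) for n, d in net.graph.degree()}
    return CentralityScores("DC", score, net.name)


def betweenness_centrality(
    net: InteractionNetwork, normalized: bool = False
) -> CentralityScores:
    """BC(i) over unordered pairs via Brandes' algorithm.

    Unreachable pairs contribute 0.  ``normalized=True`` divides by
    (n-1)(n-2)/2, which rescales but never reorders the ranking.
    """
    raw = nx.betweenness_centrality(net.graph, normalized=False)
    if normalized:
        n = net.n_nodes
        denom = (n - 1) * (n - 2) / 2.0
        if denom > 0:
            raw = {v: s / denom for v, s in raw.items()}
    return CentralityScores("BC", {v: float(s) for v, s in raw.items()}, net.name)


def closeness_centrality(
    net: InteractionNetwork, variant: str = "component"
) -> CentralityScores:
    """CC(i) = 1 / sum of shortest-path distances from i.

    ``variant="component"`` restricts the sum to i's connected component
    (nodes with no reachable partner score 0); ``variant="harmonic"`` sums
    1/d(i, j) over all j, which is well defined on disconnected graphs.
    """
    if variant not in ("component", "harmonic"):
        raise ValueError(f"unknown closeness variant {variant!r}")
    order = _node_order(net)
    n = len(order)
    if n == 0:
        return CentralityScores("CC", {}, net.name)
    dist = shortest_path(_adjacency(net, order), method="D", unweighted=True)
    score: dict[str, float] = {}
    with np.errstate(divide="ignore"):
        for i, node in enumerate(order):
            row = dist[i]
            finite = row[np.isfinite(row) & (row > 0)]
            if variant == "component":
                score[node] = float(1.0 / finite.sum()) if finite.size else 0.0
            else:
                score[node] = float((1.0 / finite).sum()) if finite.size else 0.0
    return CentralityScores("CC", score, net.name)


def _dense_eigh(net: InteractionNetwork, order: Sequence[str]):
    a = _adjacency(net, order).toarray()
    return np.linalg.eigh(a)


def subgraph_centrality(net: InteractionNetwork) -> CentralityScores:
    """SC(i) = [exp(A)]_ii: factorially weighted closed-walk count at i."""
    order = _node_order(net)
    if not order:
        return CentralityScores("SC", {}, net.name)
    w, v = _dense_eigh(net, order)
    sc = (v ** 2) @ np.exp(w)
    return CentralityScores("SC", {n: float(s) for n, s in zip(order, sc)}, net.name)


def eigenvector_centrality(
    net: InteractionNetwork, tol: float = 1e-10, maxiter: int | None = None
) -> CentralityScores:
    """EC = entrywise-absolute principal eigenvector of A, unit Euclidean norm.

    On disconnected graphs the mass concentrates on the component with the
    largest spectral radius (logged as a warning).  An edge-less network
    gets all-zero scores with a warning.
    """
    order = _node_order(net)
    n = len(order)
    if n == 0:
        return CentralityScores("EC", {}, net.name)
    if net.n_edges == 0:
        logger.warning("eigenvector centrality on an edge-less network: all zeros")
        return CentralityScores("EC", {v: 0.0 for v in order}, net.name)
    if nx.number_connected_components(net.graph) > 1:
        logger.warning(
            "eigenvector centrality on a disconnected network: scores "
            "concentrate on the component with the largest spectral radius"
        )
    a = _adjacency(net, order)
    if n <= _DENSE_EIG_LIMIT:
        w, v = np.linalg.eigh(a.toarray())
        vec = v[:, int(np.argmax(w))]
    else:
        v0 = np.full(n, 1.0 / np.sqrt(n))
        try:
            w, v = spla.eigsh(a, k=1, which="LA", tol=tol, v0=v0, maxiter=maxiter)
        except spla.ArpackNoConvergence as err:
            raise RuntimeError(
                "eigenvector centrality did not converge; retry with a dense "
                "eigendecomposition or a larger iteration cap"
            ) from err
        vec = v[:, 0]
    # sign fix then absolute value: Perron theory makes the dominant-component
    # entries one-signed, |.| cleans numerical noise elsewhere
    if vec[int(np.argmax(np.abs(vec)))] < 0:
        vec = -vec
    vec = np.abs(vec)
    vec = vec / np.linalg.norm(vec)
    return CentralityScores("EC", {nd: float(s) for nd, s in zip(order, vec)}, net.name)


def information_centrality(
    net: InteractionNetwork, variant: str = "standard"
) -> CentralityScores:
    """Current-flow information centrality per connected component.

    ``variant="standard"`` uses the pairwise information
    ``1/I_ij = r_ii + r_jj - 2 r_ij``; ``variant="unscaled"`` omits the
    factor 2 on the cross term, matching some typeset presentations of the
    formula.  Isolated nodes score 0.
    """
    if variant not in ("standard", "unscaled"):
        raise ValueError(f"unknown information-centrality variant {variant!r}")
    cross = 2.0 if variant == "standard" else 1.0
    score: dict[str, float] = {}
    for comp in nx.connected_components(net.graph):
        members = sorted(comp)
        m = len(members)
        if m == 1:
            score[members[0]] = 0.0
            continue
        a = nx.to_numpy_array(net.graph, nodelist=members, dtype=float)
        b = np.diag(a.sum(axis=1)) - a + 1.0
        r = np.linalg.inv(b)
        s = np.diag(r)
        # sum over j != i of (s_i + s_j - cross * r_ij)
        total = (m - 1) * s + (s.sum() - s) - cross * (r.sum(axis=1) - s)
        if np.any(total <= 0):
            raise ArithmeticError("non-positive information sum on a component")
        ic = m / total
        for node, val in zip(members, ic):
            score[node] = float(val)
    for node in net.graph.nodes:
        score.setdefault(node, 0.0)
    return CentralityScores("IC", score, net.name)


_DISPATCH = {
    "DC": degree_centrality,
    "BC": betweenness_centrality,
    "CC": closeness_centrality,
    "SC": subgraph_centrality,
    "EC": eigenvector_centrality,
    "IC": information_centrality,
}


def compute_all(
    net: InteractionNetwork, measures: Sequence[str] = MEASURES
) -> dict[str, CentralityScores]:
    """Compute the requested measures (default: all six) on one node set."""
    unknown = [m for m in measures if m.upper() not in _DISPATCH]
    if unknown:
        raise ValueError(f"unknown centrality measures: {unknown}")
    return {m.upper(): _DISPATCH[m.upper()](net) for m in measures}


def rank_and_select(scores: CentralityScores, k: int) -> RankedSignature:
    """Top-k genes by descending score; ties broken by gene symbol.

    If k exceeds the node count, all genes are returned with a warning.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ordered = sorted(scores.score, key=lambda g: (-scores.score[g], g))
    if k > len(ordered):
        logger.warning(
            "requested top-%d but the network has only %d genes", k, len(ordered)
        )
    return RankedSignature(measure=scores.measure, genes=ordered[:k], k=k)


@dataclass(frozen=True)
class Concordance:
    overlap: int
    jaccard: float
    p: float | None


def signature_concordance(
    sig_a: Sequence[str],
    sig_b: Sequence[str],
    universe_size: int | None = None,
    with_p: bool = False,
) -> Concordance:
    """Overlap, Jaccard index, and (optionally) hypergeometric P of two
    gene lists against a universe of ``universe_size`` genes."""
    if not sig_a or not sig_b:
        raise ValueError("both signatures must be non-empty")
    a, b = set(sig_a), set(sig_b)
    overlap = len(a & b)
    jaccard = overlap / len(a | b)
    p = None
    if with_p:
        if universe_size is None:
            raise ValueError("universe_size is required to compute a P-value")
        from censignet.enrichment import hypergeometric_tail

        p = hypergeometric_tail(universe_size, len(b), len(a), overlap)
    return Concordance(overlap=overlap, jaccard=jaccard, p=p)


def write_scores(scores: CentralityScores, path) -> None:
    """Write gene/score/rank TSV, scores at 10 significant digits."""
    from pathlib import Path

    ranked = sorted(scores.score, key=lambda g: (-scores.score[g], g))
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\tscore\trank\n")
        for rank, gene in enumerate(ranked, start=1):
            fh.write(f"{gene}\t{scores.score[gene]:.10g}\t{rank}\n")
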