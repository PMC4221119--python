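"""Protein–protein association (PPA) network: parsing, confidence filtering,
transition matrix construction and seed-proximal path reporting.

The network is an undirected graph whose nodes are genes (canonical string
Entrez IDs) and whose edges are functional associations carrying a confidence
in [0, 1], in the style of a STRING combined-score edge list.  Only
high-confidence edges (default >= 0.7) are retained; nodes left isolated by
the filter are dropped so that the column-normalized transition matrix is
well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

DEFAULT_MIN_CONFIDENCE = 0.7


class EdgeListError(ValueError):
    """Raised for malformed or unusable edge-list input."""


@dataclass
class PPANetwork:
    """Undirected confidence-filtered gene association network.

    Attributes
    ----------
    graph:
        `networkx.Graph` with a ``confidence`` attribute on every edge.
    genes:
        Lexicographically ordered tuple of gene identifiers; fixes the
        matrix layout.
    index:
        gene identifier -> 0-based matrix position.
    """

    graph: nx.Graph
    genes: tuple[str, ...] = field(init=False)
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.genes = tuple(sorted(self.graph.nodes))
        self.index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return gene in self.index

    def edge_confidence(self, a: str, b: str) -> float:
        return float(self.graph.edges[a, b]["confidence"])

    def validate(self) -> None:
        """Check structural invariants; raises AssertionError on violation."""
        assert not any(a == b for a, b in self.graph.edges), "self-edge present"
        degs = dict(self.graph.degree)
        assert all(d >= 1 for d in degs.values()), "isolated gene present"
        assert len(self.index) == len(self.genes)

    def to_edge_list(self, path: str | Path) -> None:
        """Serialize to the same TSV dialect `load_edge_list` consumes."""
        with open(path, "w") as fh:
            fh.write("#gene_a\tgene_b\tconfidence\n")
            for a, b in sorted(tuple(sorted(e)) for e in self.graph.edges):
                fh.write(f"{a}\t{b}\t{self.graph.edges[a, b]['confidence']:.6g}\n")


@dataclass
class TransitionMatrix:
    """Column-stochastic transition matrix W of the network.

    ``W[i, j]`` is the probability of stepping to gene ``i`` from gene ``j``;
    each column sums to 1.
    """

    W: np.ndarray
    genes: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.W.shape[0]


@dataclass
class SeedSet:
    """Disease-gene family mapped onto the network.

    ``p0`` places probability 1/m on each of the m seed genes present in the
    network and 0 elsewhere.
    """

    members: tuple[str, ...]
    p0: np.ndarray
    missing: tuple[str, ...] = ()

    @property
    def m(self) -> int:
        return len(self.members)


def load_edge_list(
    path: str | Path,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> PPANetwork:
    """Read a ``gene_a<TAB>gene_b<TAB>confidence`` TSV into a PPANetwork.

    Lines starting with '#' are comments.  Edges below ``min_confidence`` and
    self-edges are dropped; duplicate pairs collapse to the maximum
    confidence; genes left with degree 0 are removed.

    Raises
    ------
    EdgeListError
        On a malformed line (message names the line number), a confidence
        outside [0, 1], or an empty network after filtering.
    """
    if not 0.0 <= min_confidence <= 1.0:
        raise EdgeListError(f"min_confidence must be in [0, 1], got {min_confidence}")
    edges: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise EdgeListError(
                    f"{path}: line {lineno}: expected >=3 tab-separated columns, got {len(parts)}"
                )
            a, b, conf_str = parts[0].strip(), parts[1].strip(), parts[2].strip()
            if not a or not b:
                raise EdgeListError(f"{path}: line {lineno}: empty gene identifier")
            try:
                conf = float(conf_str)
            except ValueError as exc:
                raise EdgeListError(
                    f"{path}: line {lineno}: confidence {conf_str!r} is not a number"
                ) from exc
            if not 0.0 <= conf <= 1.0:
                raise EdgeListError(
                    f"{path}: line {lineno}: confidence {conf} outside [0, 1]"
                )
            if a == b:
                continue
            key = (a, b) if a < b else (b, a)
            edges[key] = max(edges.get(key, 0.0), conf)
    g = nx.Graph()
    for (a, b), conf in edges.items():
        if conf >= min_confidence:
            g.add_edge(a, b, confidence=conf)
    if g.number_of_nodes() == 0:
        raise EdgeListError(
            f"{path}: no edges meet confidence >= {min_confidence}; empty network"
        )
    net = PPANetwork(g)
    net.validate()
    return net


def network_from_edges(
    edges: Iterable[tuple[str, str, float]],
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> PPANetwork:
    """Build a PPANetwork from in-memory (gene_a, gene_b, confidence) triples
    with the same filtering semantics as `load_edge_list`."""
    dedup: dict[tuple[str, str], float] = {}
    for a, b, conf in edges:
        if a == b:
            continue
        if not 0.0 <= conf <= 1.0:
            raise EdgeListError(f"confidence {conf} outside [0, 1] for edge ({a}, {b})")
        key = (a, b) if a < b else (b, a)
        dedup[key] = max(dedup.get(key, 0.0), conf)
    g = nx.Graph()
    for (a, b), conf in dedup.items():
        if conf >= min_confidence:
            g.add_edge(a, b, confidence=conf)
    if g.number_of_nodes() == 0:
        raise EdgeListError("empty network after confidence filtering")
    net = PPANetwork(g)
    net.validate()
    return net


def build_transition_matrix(net: PPANetwork, weighted: bool = False) -> TransitionMatrix:
    """Column-normalized adjacency matrix of the network.

    With ``weighted=False`` (default) every retained edge contributes 1 to the
    adjacency; with ``weighted=True`` edges contribute their confidence.
    Columns sum to exactly 1 (no isolated nodes exist after filtering).
    """
    weight = "confidence" if weighted else None
    A = nx.to_numpy_array(net.graph, nodelist=net.genes, weight=weight)
    colsums = A.sum(axis=0)
    if np.any(colsums == 0):  # unreachable if net invariants hold
        raise ValueError("adjacency has a zero column; isolated gene slipped through")
    return TransitionMatrix(W=A / colsums, genes=net.genes)


def make_seed_set(net: PPANetwork, genes: Sequence[str]) -> SeedSet:
    """Map a disease-gene family onto the network as a uniform start vector.

    Genes absent from the network are reported in ``SeedSet.missing`` rather
    than silently dropped.

    Raises
    ------
    ValueError
        If no requested gene is present in the network, or the list is empty.
    """
    if not genes:
        raise ValueError("seed gene list is empty")
    members = tuple(sorted(g for g in dict.fromkeys(genes) if g in net.index))
    missing = tuple(g for g in dict.fromkeys(genes) if g not in net.index)
    if not members:
        raise ValueError(f"none of the {len(missing)} seed genes are in the network")
    p0 = np.zeros(net.n_genes)
    for g in members:
        p0[net.index[g]] = 1.0 / len(members)
    return SeedSet(members=members, p0=p0, missing=missing)


def neighbor_paths(
    net: PPANetwork, gene: str, seeds: SeedSet, max_len: int = 2
) -> list[list[tuple[str, str, float]]]:
    """All simple paths of length <= max_len (in {1, 2}) from ``gene`` to any
    seed member, each as a list of (u, v, confidence) edges.

    Deterministic order: by seed gene, then by intermediate gene.  A gene not
    in the network yields an empty list (candidates may be off-network).
    """
    if max_len not in (1, 2):
        raise ValueError("max_len must be 1 or 2")
    if gene not in net.index:
        return []
    adj = net.graph.adj
    paths: list[list[tuple[str, str, float]]] = []
    for seed in seeds.members:
        if seed == gene:
            continue
        if seed in adj[gene]:
            paths.append([(gene, seed, net.edge_confidence(gene, seed))])
        if max_len == 2:
            for mid in sorted(set(adj[gene]) & set(adj[seed])):
                if mid == gene or mid == seed:
                    continue
                paths.append(
                    [
                        (gene, mid, net.edge_confidence(gene, mid)),
                        (mid, seed, net.edge_confidence(mid, seed)),
                    ]
                )
    return paths
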