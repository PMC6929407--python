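"""Core graph and cross-network data types plus file readers/writers.

A PPI network is an undirected graph whose edges carry a confidence
weight in [0, 1] (e.g. a simGIC semantic-similarity score of the two
interactors).  Cross-network sequence similarity (e.g. -log BLAST
e-value) lives in a separate :class:`CrossLinks` table keyed by
(node-in-network-1, node-in-network-2).

File formats are headerless three-column TSV; lines starting with ``#``
and blank lines are ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Set, Tuple

import networkx as nx

logger = logging.getLogger(__name__)


class NetworkParseError(ValueError):
    """Malformed line in a network or crosslink file."""


class Network:
    """Undirected weighted PPI network.

    Thin wrapper over a :class:`networkx.Graph` enforcing the domain
    invariants: no self-loops, weights in [0, 1], string node IDs.
    Node identifiers are opaque strings scoped to one species; the two
    networks of an alignment are kept in separate ``Network`` objects so
    identical gene symbols across species never collide.
    """

    def __init__(self, name: str = ""):
        self.name = name
        self.graph = nx.Graph()

    # -- construction -------------------------------------------------
    def add_node(self, node: str) -> None:
        self.graph.add_node(str(node))

    def add_edge(self, u: str, v: str, weight: float) -> None:
        """Add an undirected edge; duplicates keep the maximum weight.

        Self-loops are silently dropped (callers that care about counts
        should pre-filter); weights outside [0, 1] raise ``ValueError``
        to surface upstream scoring mistakes rather than clamping.
        """
        u, v = str(u), str(v)
        if not 0.0 <= weight <= 1.0:
            raise ValueError(f"edge weight {weight!r} outside [0, 1] for ({u}, {v})")
        if u == v:
            return
        if self.graph.has_edge(u, v):
            if weight > self.graph[u][v]["weight"]:
                self.graph[u][v]["weight"] = weight
        else:
            self.graph.add_edge(u, v, weight=weight)

    # -- queries ------------------------------------------------------
    @property
    def nodes(self) -> Set[str]:
        return set(self.graph.nodes)

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Iterable[Tuple[str, str, float]]:
        for u, v, w in self.graph.edges(data="weight"):
            yield u, v, w

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def weight(self, u: str, v: str) -> float:
        return self.graph[u][v]["weight"]

    def neighbors(self, v: str) -> Set[str]:
        return set(self.graph.neighbors(v))

    def degree(self, v: str) -> int:
        return self.graph.degree(v)

    def weighted_degree(self, v: str) -> float:
        return sum(d["weight"] for d in self.graph[v].values())

    def induced_edges(self, members: Set[str]) -> List[Tuple[str, str, float]]:
        """Edges of the subgraph induced by ``members`` (canonical order)."""
        out = []
        for u, v, w in self.graph.subgraph(members).edges(data="weight"):
            a, b = (u, v) if u <= v else (v, u)
            out.append((a, b, w))
        out.sort()  # stable order keeps float accumulations reproducible
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        if self.nodes != other.nodes:
            return False
        mine = {tuple(sorted((u, v))): w for u, v, w in self.edges()}
        theirs = {tuple(sorted((u, v))): w for u, v, w in other.edges()}
        return mine == theirs

    def __repr__(self) -> str:
        return (
            f"Network(name={self.name!r}, nodes={len(self)}, "
            f"edges={self.number_of_edges()})"
        )


@dataclass
class CrossLinks:
    """Inter-network node-pair scores (sequence similarity, score >= 0).

    Keys are ``(node_in_g1, node_in_g2)``.  After global alignment the
    same key universe is re-scored with stationary-distribution scores.
    """

    entries: Dict[Tuple[str, str], float] = field(default_factory=dict)

    def add(self, n1: str, n2: str, score: float) -> None:
        if score < 0:
            raise ValueError(f"crosslink score {score!r} < 0 for ({n1}, {n2})")
        key = (n1, n2)
        if key not in self.entries or score > self.entries[key]:
            self.entries[key] = score

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: Tuple[str, str]) -> bool:
        return key in self.entries

    def __getitem__(self, key: Tuple[str, str]) -> float:
        return self.entries[key]

    def partners_of_g1(self, v: str) -> Dict[str, float]:
        return {n2: s for (n1, n2), s in self.entries.items() if n1 == v}

    def partners_of_g2(self, v: str) -> Dict[str, float]:
        return {n1: s for (n1, n2), s in self.entries.items() if n2 == v}


@dataclass
class Cluster:
    """A node subset of one network with its cached graph entropy.

    ``entropy`` is the whole-network entropy e(G) given this member set
    (sum of per-node binary entropies of inner-link probabilities).
    """

    network_id: str
    members: Set[str]
    entropy: float = 0.0

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _data_lines(path: str) -> Iterable[Tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_network(path: str, name: str = "") -> Network:
    """Read a headerless TSV edge list: nodeA <tab> nodeB <tab> weight.

    Duplicate edges keep the maximum weight; self-loops are dropped with
    a logged count.  Non-numeric weights or short lines raise
    :class:`NetworkParseError` naming the line; weights outside [0, 1]
    raise ``ValueError``.
    """
    net = Network(name=name or str(path))
    n_selfloops = 0
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise NetworkParseError(
                f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
            )
        u, v = fields[0], fields[1]
        try:
            w = float(fields[2])
        except ValueError as exc:
            raise NetworkParseError(
                f"{path}:{lineno}: non-numeric weight {fields[2]!r}"
            ) from exc
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"{path}:{lineno}: weight {w} outside [0, 1]")
        if u == v:
            n_selfloops += 1
            net.add_node(u)
            continue
        net.add_edge(u, v, w)
    if n_selfloops:
        logger.info("%s: dropped %d self-loop(s)", path, n_selfloops)
    return net


def write_network(net: Network, path: str) -> None:
    """Write a network back to 3-column TSV (deterministic edge order)."""
    with open(path, "w") as fh:
        for u, v, w in sorted(
            (min(a, b), max(a, b), w) for a, b, w in net.edges()
        ):
            fh.write(f"{u}\t{v}\t{w:.17g}\n")
        for v in sorted(net.nodes):
            if net.degree(v) == 0:
                fh.write(f"{v}\t{v}\t0\n")  # isolated node kept via (dropped) self-loop


def read_crosslinks(path: str, g1: Network, g2: Network) -> CrossLinks:
    """Read cross-network similarity scores: node1 <tab> node2 <tab> score.

    Entries whose endpoints are missing from the respective network are
    dropped (count logged).  Duplicate pairs keep the maximum score;
    negative scores raise ``ValueError``.
    """
    xl = CrossLinks()
    n_dropped = 0
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise NetworkParseError(
                f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
            )
        n1, n2 = fields[0], fields[1]
        try:
            score = float(fields[2])
        except ValueError as exc:
            raise NetworkParseError(
                f"{path}:{lineno}: non-numeric score {fields[2]!r}"
            ) from exc
        if score < 0:
            raise ValueError(f"{path}:{lineno}: negative score {score}")
        if n1 not in g1 or n2 not in g2:
            n_dropped += 1
            continue
        xl.add(n1, n2, score)
    if n_dropped:
        logger.info("%s: dropped %d crosslink line(s) with unmatched node IDs", path, n_dropped)
    return xl


def write_crosslinks(xl: CrossLinks, path: str) -> None:
    with open(path, "w") as fh:
        for (n1, n2), s in sorted(xl.entries.items()):
            fh.write(f"{n1}\t{n2}\t{s:.17g}\n")


def write_cluster_pairs(pairs, path1: str, path2: str) -> None:
    """Write row-aligned cluster files, one aligned pair per row.

    Row i of ``path1`` lists the members of the first cluster of pair i
    (tab-separated, sorted lexicographically); row i of ``path2`` the
    members of the second.  Both files always have identical row counts.
    """
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for pair in pairs:
            f1.write("\t".join(sorted(pair.c1.members)) + "\n")
            f2.write("\t".join(sorted(pair.c2.members)) + "\n")


def read_cluster_file(path: str) -> List[Set[str]]:
    """Read one cluster per row (tab-separated member IDs)."""
    clusters = []
    for _, line in _data_lines(path):
        clusters.append(set(line.split("\t")))
    return clusters
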