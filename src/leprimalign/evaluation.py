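"""Evaluation metrics for aligned cluster pairs.

Covers best-match f-scores against a reference complex catalog,
inter-species semantic similarity (ISS) of aligned cluster pairs,
conserved-edge counts (CE and the functionally consistent subset
F-CE), and Jaccard-based filtering of highly overlapping clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

from .network_model import CrossLinks, Network, _data_lines

logger = logging.getLogger(__name__)


@dataclass
class ComplexCatalog:
    """Reference protein complexes: (name, member set) per complex."""

    complexes: List[Tuple[str, Set[str]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.complexes)

    def member_sets(self) -> List[Set[str]]:
        return [members for _, members in self.complexes]


@dataclass
class SSTable:
    """Pairwise inter-species semantic similarities in [0, 1].

    Missing pairs read as 0.
    """

    entries: Dict[Tuple[str, str], float] = field(default_factory=dict)

    def get(self, v1: str, v2: str) -> float:
        return self.entries.get((v1, v2), 0.0)


def read_complex_catalog(
    path: str,
    restrict_to: Network | None = None,
    named: bool = False,
    min_size: int = 2,
) -> ComplexCatalog:
    """Read one complex per line (tab-separated member IDs).

    With ``named``, the first column is the complex name.  If
    ``restrict_to`` is given, members absent from that network are
    dropped; complexes falling below ``min_size`` are then discarded
    with a logged count.
    """
    catalog = ComplexCatalog()
    n_dropped = 0
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if named:
            name, members = fields[0], set(fields[1:])
        else:
            name, members = f"complex_{lineno}", set(fields)
        if restrict_to is not None:
            members &= restrict_to.nodes
        if len(members) < min_size:
            n_dropped += 1
            continue
        catalog.complexes.append((name, members))
    if n_dropped:
        logger.info("%s: dropped %d complex(es) below size %d", path, n_dropped, min_size)
    return catalog


def read_ss_table(path: str) -> SSTable:
    """Read TSV (node1, node2, similarity in [0, 1])."""
    table = SSTable()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected 3 fields")
        s = float(fields[2])
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"{path}:{lineno}: similarity {s} outside [0, 1]")
        table.entries[(fields[0], fields[1])] = s
    return table


def fscore(cluster: Set[str], complex_: Set[str]) -> float:
    """Harmonic mean of recall and precision of a cluster vs a complex."""
    if not cluster or not complex_:
        raise ValueError("cluster and complex must be non-empty")
    common = len(cluster & complex_)
    if common == 0:
        return 0.0
    rho = common / len(complex_)
    pi = common / len(cluster)
    return 2.0 * pi * rho / (pi + rho)


def mean_best_fscore(
    clusters: Sequence[Set[str]], catalog: ComplexCatalog
) -> float:
    """Mean over clusters of the best f-score over all complexes."""
    if not clusters:
        raise ValueError("need at least one cluster")
    if not len(catalog):
        raise ValueError("empty complex catalog")
    sets = catalog.member_sets()
    return sum(max(fscore(c, p) for p in sets) for c in clusters) / len(clusters)


def iss(c1: Set[str], c2: Set[str], ss: SSTable) -> float:
    """Mean semantic similarity over the full cross product C1 x C2."""
    if not c1 or not c2:
        raise ValueError("clusters must be non-empty")
    total = sum(ss.get(v1, v2) for v1 in sorted(c1) for v2 in sorted(c2))
    return total / (len(c1) * len(c2))


def _conserving_partner_edges(
    e1: Tuple[str, str],
    edges2: List[Tuple[str, str, float]],
    linked,
) -> int:
    """Count distinct partner edges conserving e1 (either orientation)."""
    vi, vj = e1
    count = 0
    for x, y, _w in edges2:
        if (linked(vi, x) and linked(vj, y)) or (linked(vi, y) and linked(vj, x)):
            count += 1
    return count


def conserved_edges(
    c1: Set[str], c2: Set[str], net1: Network, net2: Network, xl: CrossLinks
) -> int:
    """Edges of C1 directly conserved by edges of C2.

    An edge of C2 conserves an edge of C1 when both endpoint pairs are
    cross-linked (orthologous).  One C1 edge conserved by several C2
    edges contributes once per distinct C2 edge.
    """
    edges2 = net2.induced_edges(c2)

    def linked(a: str, b: str) -> bool:
        return (a, b) in xl

    total = 0
    for u, v, _w in net1.induced_edges(c1):
        total += _conserving_partner_edges((u, v), edges2, linked)
    return total


def functionally_consistent_ce(
    c1: Set[str],
    c2: Set[str],
    net1: Network,
    net2: Network,
    xl: CrossLinks,
    ss: SSTable,
    ss_threshold: float = 0.2,
) -> int:
    """Conserved edges whose endpoint pairs are also functionally
    similar: semantic similarity strictly above ``ss_threshold`` at
    both endpoints."""
    edges2 = net2.induced_edges(c2)

    def linked(a: str, b: str) -> bool:
        return (a, b) in xl and ss.get(a, b) > ss_threshold

    total = 0
    for u, v, _w in net1.induced_edges(c1):
        total += _conserving_partner_edges((u, v), edges2, linked)
    return total


def filter_overlapping(
    clusters: Sequence[Set[str]], jaccard_threshold: float = 0.4
) -> List[Set[str]]:
    """Drop highly overlapping clusters, keeping the largest.

    Greedy by descending size (ties by sorted membership): a cluster is
    kept iff its Jaccard index with every already-kept cluster is at
    most the threshold.  Idempotent.
    """
    order = sorted(clusters, key=lambda c: (-len(c), tuple(sorted(c))))
    kept: List[Set[str]] = []
    for c in order:
        ok = True
        for k in kept:
            union = len(c | k)
            if union and len(c & k) / union > jaccard_threshold:
                ok = False
                break
        if ok:
            kept.append(c)
    return kept
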