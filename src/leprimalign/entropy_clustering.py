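"""Graph-entropy machinery and seed-based initial cluster formation.

For a candidate cluster (member set) in a weighted network, each node v
has an inner-link probability p_i(v): the fraction of its weighted
degree carried by edges into the member set.  The node entropy is the
binary entropy of p_i(v) and the graph entropy e(G) is the sum over all
nodes.  Low entropy means members connect mostly inward and
non-members mostly outward — the information-theoretic notion of a
good module.

Initial clusters are grown around a seed node: start from the seed plus
all its neighbours, then greedily try removing neighbours in decreasing
weighted-degree order, keeping a removal only if it strictly lowers the
graph entropy.
"""

from __future__ import annotations

import math
from typing import Set

from .network_model import Cluster, Network

#: removals must lower entropy by more than this to count as a strict
#: decrease (guards against float noise in symmetric configurations)
_STRICT_EPS = 1e-12


def inner_probability(v: str, members: Set[str], g: Network) -> float:
    """Fraction of v's weighted degree going into ``members``.

    Isolated nodes carry no information and get p_i = 0.  On an
    unweighted graph (all weights 1) this reduces to the count ratio
    |members ∩ N(v)| / |N(v)|.
    """
    total = 0.0
    inner = 0.0
    for u, data in g.graph[v].items():
        w = data["weight"]
        total += w
        if u in members:
            inner += w
    if total == 0.0:
        return 0.0
    return inner / total


def _binary_entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -p * math.log2(p) - (1.0 - p) * math.log2(1.0 - p)


def node_entropy(v: str, members: Set[str], g: Network) -> float:
    """Binary entropy of v's inner-link probability (0·log0 := 0)."""
    return _binary_entropy(inner_probability(v, members, g))


def graph_entropy(members: Set[str], g: Network) -> float:
    """e(G): sum of node entropies over *all* nodes of the network."""
    # fixed iteration order so the float sum is reproducible
    return sum(node_entropy(v, members, g) for v in sorted(g.graph.nodes))


def form_initial_cluster(seed: str, g: Network) -> Cluster:
    """Grow the seed cluster: seed + neighbours, then greedy removal.

    Neighbours are visited once each, in decreasing weighted-degree
    order (ties broken lexicographically); a tentative removal is kept
    only if the graph entropy strictly decreases.  The seed itself is
    never removed.  Entropy deltas are evaluated incrementally —
    removing node r only changes the node entropy of r's neighbours —
    which is exactly equal to a full recomputation.

    An isolated seed yields the singleton cluster (filtered later by
    the minimum-size rule).
    """
    if seed not in g:
        raise KeyError(f"seed node {seed!r} not in network {g.name!r}")
    neighbors = g.neighbors(seed)
    members = {seed} | neighbors
    total = graph_entropy(members, g)

    order = sorted(neighbors, key=lambda v: (-g.weighted_degree(v), v))
    for r in order:
        affected = sorted(g.neighbors(r))  # fixed order: reproducible sums
        before = sum(node_entropy(v, members, g) for v in affected)
        members.discard(r)
        after = sum(node_entropy(v, members, g) for v in affected)
        delta = after - before
        if delta < -_STRICT_EPS:
            total += delta
        else:
            members.add(r)

    return Cluster(network_id=g.name, members=members, entropy=total)
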