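"""The local alignment engine: seeds, match/gap scoring, expansion.

Seed pairs are cross-network node pairs whose global alignment score
exceeds a threshold theta.  Around each seed an initial cluster is
formed in each network by entropy minimisation, and the pair is then
expanded greedily: boundary nodes are admitted whenever they raise the
cluster's own directional local score

    S_local(C1, C2) = gamma * S_inter + (1 - gamma) * S_intra

S_intra rewards edges of C1 conserved in C2 either directly (a match:
both endpoints aligned to adjacent nodes of C2) or through one
unaligned intermediate node (a gap, discounted by beta).  S_inter is
the mean, over C1's nodes, of the best normalised global score into
C2.  Pairs whose final clusters are too small or score below a floor
are discarded to prevent degenerate output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Set, Tuple

from .entropy_clustering import form_initial_cluster
from .global_align import GlobalAlignment, GlobalConfig, run_global_alignment
from .network_model import Cluster, CrossLinks, Network

logger = logging.getLogger(__name__)


@dataclass
class Params:
    """Local-alignment parameters.

    theta   -- seed threshold on the raw global score S_global.
    beta    -- gap penalty in [0, 1]; 1 treats gaps like matches.
    gamma   -- weight of the inter-network term in S_local.
    min_size -- minimum members per emitted cluster.
    discard_threshold -- floor on both directional S_local scores.
    """

    theta: float = 1.0
    beta: float = 1.0
    gamma: float = 0.25
    min_size: int = 2
    discard_threshold: float = 0.02

    def __post_init__(self):
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")


@dataclass
class EdgeClassification:
    """Disjoint match/gap subsets of one cluster's internal edges.

    Edges are canonical (sorted) node pairs.  An edge qualifying as
    both counts as a match only.
    """

    match: Set[Tuple[str, str]] = field(default_factory=set)
    gap: Set[Tuple[str, str]] = field(default_factory=set)


@dataclass
class ClusterPair:
    """Two aligned clusters with their bidirectional local scores."""

    c1: Cluster
    c2: Cluster
    s_local_12: float
    s_local_21: float
    seed: Tuple[str, str] = ("", "")


def select_seeds(
    ga: GlobalAlignment, theta: float
) -> List[Tuple[str, str]]:
    """All pairs with S_global > theta, by descending score then IDs."""
    hits = [(pair, s) for pair, s in ga.scores.items() if s > theta]
    hits.sort(key=lambda item: (-item[1], item[0]))
    return [pair for pair, _ in hits]


def classify_edges(
    members_a: Set[str],
    members_b: Set[str],
    net_a: Network,
    net_b: Network,
    aligned: Callable[[str, str], bool],
) -> EdgeClassification:
    """Classify cluster A's internal edges as matches or gaps w.r.t. B.

    ``aligned(u, v)`` must accept (node in net_a, node in net_b).  An
    edge (vi, vj) of A is a *match* if some aligned partners vi', vj'
    in B are themselves adjacent in B; it is a *gap* if, failing that,
    partners exist that are joined by a 2-edge path through an
    intermediate member of B aligned to no node of A.  Partners three
    or more hops apart confer nothing.
    """
    partners: Dict[str, Set[str]] = {
        v: {u for u in members_b if aligned(v, u)} for v in members_a
    }
    aligned_b = set().union(*partners.values()) if partners else set()
    unaligned_b = members_b - aligned_b

    cls = EdgeClassification()
    for vi, vj, _w in net_a.induced_edges(members_a):
        pi, pj = partners[vi], partners[vj]
        if not pi or not pj:
            continue
        is_match = any(
            net_b.has_edge(x, y) for x in pi for y in pj if x != y
        )
        if is_match:
            cls.match.add((vi, vj))
            continue
        is_gap = False
        for x in pi:
            for m in net_b.neighbors(x) & unaligned_b:
                if net_b.neighbors(m) & (pj - {x}):
                    is_gap = True
                    break
            if is_gap:
                break
        if is_gap:
            cls.gap.add((vi, vj))
    return cls


def intra_score(
    members_a: Set[str],
    net_a: Network,
    cls: EdgeClassification,
    beta: float,
) -> float:
    """(sum of match weights + beta * sum of gap weights) / |E_A|.

    Clusters with no internal edges score 0.
    """
    edges = net_a.induced_edges(members_a)
    if not edges:
        return 0.0
    match_w = sum(w for u, v, w in edges if (u, v) in cls.match)
    gap_w = sum(w for u, v, w in edges if (u, v) in cls.gap)
    return (match_w + beta * gap_w) / len(edges)


def inter_score(
    members_a: Set[str],
    members_b: Set[str],
    ga: GlobalAlignment,
    direction: str = "12",
) -> float:
    """Mean over A's nodes of the best S_norm into B (0 if none).

    All cross-linked pairs count, with no threshold.  ``direction``
    says which side of the score keys A sits on ("12": A is network 1).
    """
    if not members_a:
        return 0.0
    total = 0.0
    for v in sorted(members_a):  # fixed order: reproducible float sums
        best = 0.0
        for u in members_b:
            key = (v, u) if direction == "12" else (u, v)
            s = ga.norm_scores.get(key, 0.0)
            if s > best:
                best = s
        total += best
    return total / len(members_a)


def local_score(
    members_a: Set[str],
    members_b: Set[str],
    net_a: Network,
    net_b: Network,
    ga: GlobalAlignment,
    beta: float,
    gamma: float,
    direction: str = "12",
) -> float:
    """Directional S_local of cluster A against cluster B."""
    if direction == "12":
        aligned = ga.aligned
    else:
        aligned = lambda u, v: ga.aligned(v, u)  # noqa: E731
    cls = classify_edges(members_a, members_b, net_a, net_b, aligned)
    s_intra = intra_score(members_a, net_a, cls, beta)
    s_inter = inter_score(members_a, members_b, ga, direction)
    return gamma * s_inter + (1.0 - gamma) * s_intra


def _boundary(members: Set[str], net: Network) -> List[str]:
    """Outside nodes with >=1 edge into the cluster, by descending
    (unweighted) degree, ties lexicographic."""
    boundary = set()
    for v in members:
        boundary |= net.neighbors(v)
    boundary -= members
    return sorted(boundary, key=lambda v: (-net.degree(v), v))


def expand_pair(
    c1: Cluster,
    c2: Cluster,
    g1: Network,
    g2: Network,
    ga: GlobalAlignment,
    params: Params,
    seed: Tuple[str, str] = ("", ""),
    trace: List[Tuple[str, str, float, float]] | None = None,
) -> ClusterPair:
    """Greedy simultaneous expansion of an aligned cluster pair.

    Repeats passes until a fixpoint: each pass enumerates the outer
    boundary of C1 (then C2) in descending degree order and accepts a
    node iff it strictly increases that cluster's own directional
    score.  Accepting a node on one side can change both directional
    scores, so both are refreshed after every acceptance.

    If ``trace`` is a list, every accepted addition appends
    ``(side, node, score_before, score_after)``.
    """
    m1 = set(c1.members)
    m2 = set(c2.members)
    s12 = local_score(m1, m2, g1, g2, ga, params.beta, params.gamma, "12")
    s21 = local_score(m2, m1, g2, g1, ga, params.beta, params.gamma, "21")

    while True:
        accepted_any = False
        for cand in _boundary(m1, g1):
            trial = m1 | {cand}
            s = local_score(trial, m2, g1, g2, ga, params.beta, params.gamma, "12")
            if s > s12:
                if trace is not None:
                    trace.append(("c1", cand, s12, s))
                m1 = trial
                s12 = s
                s21 = local_score(m2, m1, g2, g1, ga, params.beta, params.gamma, "21")
                accepted_any = True
        for cand in _boundary(m2, g2):
            trial = m2 | {cand}
            s = local_score(trial, m1, g2, g1, ga, params.beta, params.gamma, "21")
            if s > s21:
                if trace is not None:
                    trace.append(("c2", cand, s21, s))
                m2 = trial
                s21 = s
                s12 = local_score(m1, m2, g1, g2, ga, params.beta, params.gamma, "12")
                accepted_any = True
        if not accepted_any:
            break

    from .entropy_clustering import graph_entropy

    return ClusterPair(
        c1=Cluster(network_id=g1.name, members=m1, entropy=graph_entropy(m1, g1)),
        c2=Cluster(network_id=g2.name, members=m2, entropy=graph_entropy(m2, g2)),
        s_local_12=s12,
        s_local_21=s21,
        seed=seed,
    )


def align(
    g1: Network,
    g2: Network,
    xl: CrossLinks,
    params: Params | None = None,
    global_cfg: GlobalConfig | None = None,
) -> List[ClusterPair]:
    """End-to-end local alignment of two networks.

    Runs the global Markov-chain alignment, selects seed pairs above
    theta, and for each unvisited seed forms and expands an aligned
    cluster pair.  A pair is emitted only if both final clusters reach
    the minimum size and both directional scores reach the discard
    floor; its members are then marked visited.  A seed is skipped only
    when *both* endpoints are already visited.
    """
    params = params or Params()
    ga = run_global_alignment(g1, g2, xl, global_cfg)
    seeds = select_seeds(ga, params.theta)
    if not seeds:
        logger.warning("no seed pairs with S_global > theta=%g", params.theta)
        return []

    visited1: Set[str] = set()
    visited2: Set[str] = set()
    out: List[ClusterPair] = []
    for v1, v2 in seeds:
        if v1 in visited1 and v2 in visited2:
            continue
        c1 = form_initial_cluster(v1, g1)
        c2 = form_initial_cluster(v2, g2)
        pair = expand_pair(c1, c2, g1, g2, ga, params, seed=(v1, v2))
        if (
            len(pair.c1) >= params.min_size
            and len(pair.c2) >= params.min_size
            and pair.s_local_12 >= params.discard_threshold
            and pair.s_local_21 >= params.discard_threshold
        ):
            out.append(pair)
            visited1 |= pair.c1.members
            visited2 |= pair.c2.members
    return out
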