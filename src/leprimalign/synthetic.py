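"""Deterministic generator of paired networks with planted modules.

Emulates the inputs of the aligner: two weighted PPI networks whose
edge weights mimic semantic-similarity confidences, a cross-network
similarity table mimicking -log BLAST e-values, and a ground-truth
list of conserved module pairs.  Network 1 carries dense planted
modules over a sparse random background; network 2 carries relabelled
copies of the same modules with per-edge dropout plus its own
background.  Counterpart nodes are cross-linked at a high "ortholog"
score level; a configurable number of spurious cross-links at a
strictly lower score level emulate chance sequence hits.

All randomness flows from the single integer seed in the spec; no
global random state is touched.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import List, Set, Tuple

import numpy as np

from .network_model import CrossLinks, Network

logger = logging.getLogger(__name__)

#: resample cap for the module-density invariant
_MAX_REDRAWS = 100


@dataclass
class SyntheticSpec:
    """Parameters of a planted-module instance.

    Module edges are dense (probability ``p_in``) and high-confidence;
    background edges are sparse (``p_bg``) and low-confidence, giving
    the intra/inter contrast real conserved complexes show.  Planted
    counterpart cross-link scores must strictly exceed the spurious
    level so orthology is detectable in principle.
    """

    n_modules: int = 3
    module_size: Tuple[int, int] = (6, 6)  # inclusive range
    p_in: float = 0.9
    n_background: int = 20
    p_bg: float = 0.05
    module_weight: Tuple[float, float] = (0.6, 1.0)
    background_weight: Tuple[float, float] = (0.05, 0.4)
    ortholog_score: float = 50.0
    spurious_rate: float = 0.5  # spurious links per planted counterpart link
    spurious_score: float = 2.0
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_modules < 1:
            raise ValueError("need at least one module")
        if self.module_size[0] < 2 or self.module_size[0] > self.module_size[1]:
            raise ValueError("module_size must be a range with minimum >= 2")
        if not self.p_in > self.p_bg:
            raise ValueError("p_in must exceed p_bg")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.ortholog_score <= self.spurious_score:
            raise ValueError("ortholog_score must strictly exceed spurious_score")
        if self.n_background < 0 or self.spurious_rate < 0:
            raise ValueError("counts/rates must be non-negative")


def _draw_module_edges(
    size: int, p_in: float, p_bg: float, rng: np.random.Generator
) -> List[Tuple[int, int]]:
    """Bernoulli(p_in) edges over a module, redrawn until the realised
    density beats the background density (logged when it happens)."""
    pairs = list(itertools.combinations(range(size), 2))
    for attempt in range(_MAX_REDRAWS):
        mask = rng.random(len(pairs)) < p_in
        edges = [pairs[i] for i in np.flatnonzero(mask)]
        if len(edges) / len(pairs) > p_bg:
            if attempt:
                logger.info("module redrawn %d time(s) to satisfy density contrast", attempt)
            return edges
    raise RuntimeError("could not realise a module denser than background")


def generate_pair(
    spec: SyntheticSpec,
) -> Tuple[Network, Network, CrossLinks, List[Tuple[Set[str], Set[str]]]]:
    """Build (G1, G2, crosslinks, ground-truth module pairs).

    Fully reproducible from ``spec.seed``; the same spec yields
    byte-identical outputs on every call.
    """
    rng = np.random.default_rng(spec.seed)
    g1 = Network(name="net1")
    g2 = Network(name="net2")
    xl = CrossLinks()
    truth: List[Tuple[Set[str], Set[str]]] = []

    lo_w, hi_w = spec.module_weight
    lo_b, hi_b = spec.background_weight

    # planted modules and their counterparts
    module_nodes1: List[List[str]] = []
    module_nodes2: List[List[str]] = []
    for k in range(spec.n_modules):
        size = int(rng.integers(spec.module_size[0], spec.module_size[1] + 1))
        names1 = [f"g1_m{k}_{i}" for i in range(size)]
        names2 = [f"g2_m{k}_{i}" for i in range(size)]
        for v in names1:
            g1.add_node(v)
        for v in names2:
            g2.add_node(v)
        edges = _draw_module_edges(size, spec.p_in, spec.p_bg, rng)
        for i, j in edges:
            w = float(rng.uniform(lo_w, hi_w))
            g1.add_edge(names1[i], names1[j], w)
            if rng.random() >= spec.dropout:  # counterpart edge survives
                g2.add_edge(names2[i], names2[j], w)
        module_nodes1.append(names1)
        module_nodes2.append(names2)
        truth.append((set(names1), set(names2)))

    # background nodes and sparse noise edges (skipping intra-module pairs)
    bg1 = [f"g1_bg_{i}" for i in range(spec.n_background)]
    bg2 = [f"g2_bg_{i}" for i in range(spec.n_background)]
    for v in bg1:
        g1.add_node(v)
    for v in bg2:
        g2.add_node(v)

    for net, bg, modules in ((g1, bg1, module_nodes1), (g2, bg2, module_nodes2)):
        module_of = {}
        for k, names in enumerate(modules):
            for v in names:
                module_of[v] = k
        all_nodes = sorted(net.nodes)
        for u, v in itertools.combinations(all_nodes, 2):
            if (
                u in module_of
                and v in module_of
                and module_of[u] == module_of[v]
            ):
                continue
            if rng.random() < spec.p_bg:
                net.add_edge(u, v, float(rng.uniform(lo_b, hi_b)))

    # counterpart (ortholog) crosslinks: jittered but always above spurious
    true_pairs = []
    for names1, names2 in zip(module_nodes1, module_nodes2):
        for a, b in zip(names1, names2):
            true_pairs.append((a, b))
    floor = spec.spurious_score / spec.ortholog_score
    for a, b in true_pairs:
        jitter = float(rng.uniform(max(0.8, floor * 1.5), 1.2))
        xl.add(a, b, spec.ortholog_score * jitter)

    # spurious crosslinks at a strictly lower score level
    n_spurious = int(round(spec.spurious_rate * len(true_pairs)))
    nodes1 = sorted(g1.nodes)
    nodes2 = sorted(g2.nodes)
    taken = set(true_pairs)
    attempts = 0
    while n_spurious > 0 and attempts < 100 * (n_spurious + 1):
        a = nodes1[int(rng.integers(len(nodes1)))]
        b = nodes2[int(rng.integers(len(nodes2)))]
        attempts += 1
        if (a, b) in taken:
            continue
        taken.add((a, b))
        xl.add(a, b, spec.spurious_score * float(rng.uniform(0.2, 1.0)))
        n_spurious -= 1

    return g1, g2, xl, truth


def write_truth(
    truth: List[Tuple[Set[str], Set[str]]], path1: str, path2: str
) -> None:
    """Row-aligned ground-truth files mirroring the aligner's output."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for m1, m2 in truth:
            f1.write("\t".join(sorted(m1)) + "\n")
            f2.write("\t".join(sorted(m2)) + "\n")
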