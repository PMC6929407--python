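"""Shared fixtures, builders, and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from leprimalign import CrossLinks, Network


def make_network(edges, name="net", extra_nodes=()):
    """Build a Network from (u, v, w) triples."""
    net = Network(name=name)
    for u, v, w in edges:
        net.add_edge(u, v, w)
    for v in extra_nodes:
        net.add_node(v)
    return net


def make_crosslinks(entries):
    xl = CrossLinks()
    for n1, n2, s in entries:
        xl.add(n1, n2, s)
    return xl


@pytest.fixture
def four_node_graph():
    """s-a, s-b, a-b, b-x, all weights 1: the worked entropy example."""
    return make_network(
        [("s", "a", 1.0), ("s", "b", 1.0), ("a", "b", 1.0), ("b", "x", 1.0)]
    )


def random_instance(rng, n1=None, n2=None, p_edge=0.3, p_cross=0.3):
    """Random weighted network pair plus crosslinks for oracle tests."""
    n1 = n1 or int(rng.integers(3, 12))
    n2 = n2 or int(rng.integers(3, 12))
    g1 = Network(name="net1")
    g2 = Network(name="net2")
    for i in range(n1):
        g1.add_node(f"a{i}")
    for j in range(n2):
        g2.add_node(f"b{j}")
    for i in range(n1):
        for j in range(i + 1, n1):
            if rng.random() < p_edge:
                g1.add_edge(f"a{i}", f"a{j}", float(rng.uniform(0.05, 1.0)))
    for i in range(n2):
        for j in range(i + 1, n2):
            if rng.random() < p_edge:
                g2.add_edge(f"b{i}", f"b{j}", float(rng.uniform(0.05, 1.0)))
    xl = CrossLinks()
    for i in range(n1):
        for j in range(n2):
            if rng.random() < p_cross:
                xl.add(f"a{i}", f"b{j}", float(rng.uniform(0.1, 20.0)))
    return g1, g2, xl


def dense_stationary(g1, g2, xl, cross_weight=1.0, alpha=0.85, tol=1e-12, max_iter=5000):
    """Brute-force dense power-method oracle for the stationary
    distribution, built straight from the inputs with plain numpy.

    Independent of the sparse implementation: assembles a dense raw
    matrix, row-normalises it with explicit loops, and iterates the
    damped update with dangling-mass teleportation.
    """
    nodes1 = sorted(g1.nodes)
    nodes2 = sorted(g2.nodes)
    idx = {v: i for i, v in enumerate(nodes1)}
    idx.update({v: len(nodes1) + j for j, v in enumerate(nodes2)})
    n = len(nodes1) + len(nodes2)
    A = np.zeros((n, n))
    for u, v, w in g1.edges():
        A[idx[u], idx[v]] = w
        A[idx[v], idx[u]] = w
    for u, v, w in g2.edges():
        A[idx[u], idx[v]] = w
        A[idx[v], idx[u]] = w
    for (v1, v2), s in xl.entries.items():
        A[idx[v1], idx[v2]] = cross_weight * s
        A[idx[v2], idx[v1]] = cross_weight * s
    T = np.zeros_like(A)
    q = np.zeros(n)
    for i in range(n):
        rs = A[i].sum()
        if rs > 0:
            T[i] = A[i] / rs
        else:
            q[i] = 1.0
    p = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        p_temp = alpha * (p @ T) + (alpha * float(p @ q) + 1.0 - alpha) / n
        p_new = p_temp / np.abs(p_temp).sum()
        if np.abs(p_new - p).sum() < tol:
            return p_new
        p = p_new
    return p
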