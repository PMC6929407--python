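"""Markov-chain global alignment of two interconnected PPI networks.

The two networks plus their cross-network sequence-similarity links are
modelled as a single Markov chain.  The transition matrix has four
blocks: within-network blocks built from interaction confidences and
cross-network blocks built from weighted sequence-similarity scores;
each row is normalised to sum to 1 (rows with no outgoing mass are
"dangling" and handled by the teleport correction).  Power iteration
with damping yields the stationary distribution, from which every
cross-linked node pair receives a global alignment score

    S_global(v1, v2) = (p(v1) * s12 + p(v2) * s21) * n

where s12 is the fraction of v1's cross-network transition mass that
goes to v2 (and symmetrically s21), and n is the total node count.
Scores are finally log-normalised into [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import scipy.sparse as sp

from .network_model import CrossLinks, Network

logger = logging.getLogger(__name__)


@dataclass
class GlobalConfig:
    """Knobs of the global-alignment preprocessing stage.

    alpha        -- PageRank damping factor (standard convention 0.85).
    cross_weight -- multiplier applied to raw sequence-similarity scores
                    when they enter the transition matrix.
    tol          -- L1 convergence tolerance of the power iteration.
    max_iter     -- iteration cap; hitting it logs a warning.
    """

    alpha: float = 0.85
    cross_weight: float = 1.0
    tol: float = 1e-10
    max_iter: int = 1000


@dataclass
class TransitionMatrix:
    """Row-stochastic transition matrix over both networks' nodes.

    Rows/columns 0..n1-1 are network-1 nodes (sorted), n1..n-1 are
    network-2 nodes (sorted).  ``q`` flags dangling (all-zero) rows.
    ``cross_sum1[i]`` is the total raw cross-network mass of network-1
    node i (used to turn matrix entries back into per-pair shares).
    """

    T: sp.csr_matrix
    q: np.ndarray
    n1: int
    n2: int
    nodes1: List[str]
    nodes2: List[str]
    idx1: Dict[str, int] = field(repr=False, default_factory=dict)
    idx2: Dict[str, int] = field(repr=False, default_factory=dict)
    cross_sum1: np.ndarray = field(repr=False, default=None)
    cross_sum2: np.ndarray = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return self.n1 + self.n2


@dataclass
class GlobalAlignment:
    """Per cross-linked pair: raw score S_global and normalised S_norm."""

    scores: Dict[Tuple[str, str], float]
    norm_scores: Dict[Tuple[str, str], float] = field(default_factory=dict)
    base: int = 0

    def aligned(self, v1: str, v2: str) -> bool:
        """Whether (v1 in G1, v2 in G2) count as aligned for match/gap
        classification: any cross-link-derived score strictly above 0."""
        return self.scores.get((v1, v2), 0.0) > 0.0


def build_transition_matrix(
    g1: Network, g2: Network, xl: CrossLinks, cross_weight: float = 1.0
) -> TransitionMatrix:
    """Assemble and row-normalise the 4-block transition matrix.

    Raw within-network entries are edge weights; raw cross entries are
    ``cross_weight * sequence similarity``.  Rows with zero total mass
    stay zero and are flagged dangling.
    """
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both networks must be non-empty")
    if cross_weight <= 0:
        raise ValueError("cross_weight must be > 0")

    nodes1 = sorted(g1.nodes)
    nodes2 = sorted(g2.nodes)
    idx1 = {v: i for i, v in enumerate(nodes1)}
    idx2 = {v: i for i, v in enumerate(nodes2)}
    n1, n2 = len(nodes1), len(nodes2)
    n = n1 + n2

    rows: List[int] = []
    cols: List[int] = []
    vals: List[float] = []

    for u, v, w in g1.edges():
        i, j = idx1[u], idx1[v]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    for u, v, w in g2.edges():
        i, j = n1 + idx2[u], n1 + idx2[v]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]

    cross_sum1 = np.zeros(n1)
    cross_sum2 = np.zeros(n2)
    for (v1, v2), s in xl.entries.items():
        i, j = idx1[v1], idx2[v2]
        w = cross_weight * s
        rows += [i, n1 + j]
        cols += [n1 + j, i]
        vals += [w, w]
        cross_sum1[i] += w
        cross_sum2[j] += w

    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    A.sum_duplicates()
    row_sums = np.asarray(A.sum(axis=1)).ravel()
    q = (row_sums == 0).astype(float)
    inv = np.divide(1.0, row_sums, out=np.zeros_like(row_sums), where=row_sums > 0)
    T = sp.diags(inv) @ A
    return TransitionMatrix(
        T=T.tocsr(),
        q=q,
        n1=n1,
        n2=n2,
        nodes1=nodes1,
        nodes2=nodes2,
        idx1=idx1,
        idx2=idx2,
        cross_sum1=cross_sum1,
        cross_sum2=cross_sum2,
    )


def stationary_distribution(
    tm: TransitionMatrix,
    alpha: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> np.ndarray:
    """Damped power iteration with dangling-node teleport correction.

    Each step computes

        p_temp = alpha * p T + (alpha * p.q + 1 - alpha) * u / n
        p      = p_temp / ||p_temp||_1

    starting from the uniform distribution, and stops once the L1
    change between successive iterates drops below ``tol``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    n = tm.n
    p = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        dangling_mass = float(p @ tm.q)
        p_temp = alpha * (p @ tm.T) + (alpha * dangling_mass + 1.0 - alpha) / n
        p_new = p_temp / np.abs(p_temp).sum()
        if np.abs(p_new - p).sum() < tol:
            return p_new
        p = p_new
    logger.warning("power iteration hit max_iter=%d without reaching tol=%g", max_iter, tol)
    return p


def global_scores(
    p: np.ndarray, tm: TransitionMatrix, xl: CrossLinks
) -> GlobalAlignment:
    """Score every cross-linked pair from the stationary distribution.

    The share terms are each pair's fraction of its node's total raw
    cross-network mass; the within-network edges do not enter here
    (they already shaped p).
    """
    scores: Dict[Tuple[str, str], float] = {}
    n = tm.n
    for (v1, v2), s in xl.entries.items():
        i, j = tm.idx1[v1], tm.idx2[v2]
        share1 = s / tm.cross_sum1[i] if tm.cross_sum1[i] > 0 else 0.0
        share2 = s / tm.cross_sum2[j] if tm.cross_sum2[j] > 0 else 0.0
        scores[(v1, v2)] = (p[i] * share1 + p[tm.n1 + j] * share2) * n
    return GlobalAlignment(scores=scores)


def normalize_scores(ga: GlobalAlignment) -> GlobalAlignment:
    """Log-normalise raw scores into [0, 1].

    The base is ceil(1 + max score), floored at 2 so the logarithm is
    valid on degenerate inputs where every score is below 1.  The pair
    attaining the maximum maps to 1 exactly when 1 + max is integral;
    zero scores map to 0.
    """
    if not ga.scores:
        raise ValueError("cannot normalise an empty score map")
    max_score = max(ga.scores.values())
    base = max(2, math.ceil(1.0 + max_score))
    log_b = math.log(base)
    ga.base = base
    ga.norm_scores = {
        pair: math.log1p(s) / log_b for pair, s in ga.scores.items()
    }
    return ga


def dump_global_scores(ga: GlobalAlignment, path: str) -> None:
    """TSV dump (node1, node2, S_global, S_norm) for inspection/reuse."""
    with open(path, "w") as fh:
        for (v1, v2), s in sorted(ga.scores.items()):
            fh.write(f"{v1}\t{v2}\t{s:.17g}\t{ga.norm_scores.get((v1, v2), 0.0):.17g}\n")


def run_global_alignment(
    g1: Network, g2: Network, xl: CrossLinks, cfg: GlobalConfig | None = None
) -> GlobalAlignment:
    """Full preprocessing pipeline: matrix, stationary p, scores, norms."""
    cfg = cfg or GlobalConfig()
    tm = build_transition_matrix(g1, g2, xl, cross_weight=cfg.cross_weight)
    p = stationary_distribution(tm, alpha=cfg.alpha, tol=cfg.tol, max_iter=cfg.max_iter)
    ga = global_scores(p, tm, xl)
    if ga.scores:
        normalize_scores(ga)
    return ga
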