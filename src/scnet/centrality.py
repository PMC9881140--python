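"""Weighted-degree centrality, percentile ranks, and hub significance.

Centrality is the *strength* of a gene: the sum of LLS weights of its
incident edges.  Hubness is tested against a rewiring null: degree-preserving
double-edge swaps randomize the wiring while every edge keeps its weight, the
strengths of all genes across replicates are pooled into one null
distribution, and each gene's strength is ranked within it (empirical p with
a pseudo-count, Benjamini-Hochberg across genes).  Ribosomal proteins, which
dominate interactome degree for technical reasons, are excluded from hub
calls by default.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import networkx as nx
from statsmodels.stats.multitest import multipletests

from .defaults import FDR_CUT, HUB_N_NULL, SWAPS_PER_EDGE
from .exclusion import default_exclusion

logger = logging.getLogger(__name__)

__all__ = [
    "weighted_degree",
    "percentile_rank",
    "rewire_network",
    "find_all_hubs",
]


def weighted_degree(net: nx.Graph) -> dict[str, float]:
    """Strength of every node: sum of incident edge weights (isolates -> 0)."""
    if net.number_of_nodes() == 0:
        raise ValueError("network has no nodes")
    return {g: float(s) for g, s in net.degree(weight="weight")}


def percentile_rank(strengths: Mapping[str, float]) -> dict[str, float]:
    """Percentile rank of each gene's strength, in [0, 1].

    PR = (rank - 1) / (n - 1) with minimum rank for ties (rank = 1 + number
    of genes with strictly smaller strength), so the most central gene scores
    1 and the least central 0.  A single gene scores 1.0 by convention.
    """
    genes = list(strengths)
    n = len(genes)
    if n == 0:
        raise ValueError("empty strength map")
    if n == 1:
        return {genes[0]: 1.0}
    values = np.array([strengths[g] for g in genes], dtype=float)
    order = np.sort(values)
    below = np.searchsorted(order, values, side="left")  # strictly smaller
    return {g: float(b) / (n - 1) for g, b in zip(genes, below)}


# ---------------------------------------------------------------------------
# degree-preserving rewiring


def _edge_arrays(net: nx.Graph) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    nodes = sorted(net.nodes)
    index = {g: i for i, g in enumerate(nodes)}
    m = net.number_of_edges()
    u = np.empty(m, dtype=np.int64)
    v = np.empty(m, dtype=np.int64)
    w = np.empty(m, dtype=float)
    for k, (a, b, weight) in enumerate(sorted(net.edges(data="weight"))):
        u[k], v[k], w[k] = index[a], index[b], weight
    return nodes, u, v, w


def _swap_edges(
    u: np.ndarray, v: np.ndarray, n_attempts: int, rng: np.random.Generator
) -> int:
    """In-place double-edge swaps; returns the number of accepted swaps.

    A proposal picks two distinct edges (a,b), (c,d) (with the second edge's
    orientation coin-flipped) and rewires them to (a,d), (c,b); it is
    rejected if it would create a self-loop or a duplicate edge.  Degrees are
    invariant; each edge keeps its weight.
    """
    m = len(u)
    if m < 2:
        return 0
    edge_set = {(int(a), int(b)) if a < b else (int(b), int(a)) for a, b in zip(u, v)}
    picks = rng.integers(0, m, size=(n_attempts, 2))
    flips = rng.random(n_attempts) < 0.5
    accepted = 0
    for k in range(n_attempts):
        i, j = picks[k]
        if i == j:
            continue
        a, b = int(u[i]), int(v[i])
        c, d = int(u[j]), int(v[j])
        if flips[k]:
            c, d = d, c
        if a == d or c == b:
            continue
        e1 = (a, d) if a < d else (d, a)
        e2 = (c, b) if c < b else (b, c)
        if e1 == e2 or e1 in edge_set or e2 in edge_set:
            continue
        edge_set.remove((a, b) if a < b else (b, a))
        edge_set.remove((c, d) if c < d else (d, c))
        edge_set.add(e1)
        edge_set.add(e2)
        u[i], v[i] = a, d
        u[j], v[j] = c, b
        accepted += 1
    return accepted


def rewire_network(
    net: nx.Graph,
    n_swaps: int | None = None,
    seed: int | np.random.Generator | None = None,
    shuffle_weights: bool = False,
) -> nx.Graph:
    """One degree-preserving rewired replicate of ``net``.

    ``n_swaps`` defaults to ``SWAPS_PER_EDGE * |E|`` swap attempts.  Weights
    travel with their edges unless ``shuffle_weights`` is set, in which case
    they are additionally permuted across the rewired edges.

    Raises ``ValueError`` when the network has fewer than 3 edges (the swap
    move is then undefined).  A replicate in which every attempt is rejected
    (e.g. a star, whose wiring is the unique graph with its degree sequence)
    is returned unchanged with a warning.
    """
    if net.number_of_edges() < 3:
        raise ValueError(
            "network too small to rewire: need at least 3 edges for "
            "degree-preserving double-edge swaps"
        )
    rng = np.random.default_rng(seed)
    nodes, u, v, w = _edge_arrays(net)
    if n_swaps is None:
        n_swaps = SWAPS_PER_EDGE * len(u)
    accepted = _swap_edges(u, v, n_swaps, rng)
    if accepted == 0:
        logger.warning(
            "rewiring accepted 0/%d swaps; replicate equals the input network",
            n_swaps,
        )
    if shuffle_weights:
        w = rng.permutation(w)
    out = nx.Graph()
    out.add_nodes_from(nodes)
    for i in range(len(u)):
        out.add_edge(nodes[u[i]], nodes[v[i]], weight=float(w[i]))
    out.graph.update(net.graph)
    return out


def _null_strength_pool(
    net: nx.Graph,
    n_null: int,
    rng: np.random.Generator,
    shuffle_weights: bool = False,
) -> np.ndarray:
    """Pooled strengths of all genes over rewired replicates (>= n_null)."""
    nodes, u0, v0, w = _edge_arrays(net)
    n_nodes = len(nodes)
    n_swaps = SWAPS_PER_EDGE * len(u0)
    n_replicates = max(1, math.ceil(n_null / n_nodes))
    pool = np.empty(n_replicates * n_nodes, dtype=float)
    total_accepted = 0
    for r in range(n_replicates):
        u, v = u0.copy(), v0.copy()
        total_accepted += _swap_edges(u, v, n_swaps, rng)
        wr = rng.permutation(w) if shuffle_weights else w
        s = np.zeros(n_nodes)
        np.add.at(s, u, wr)
        np.add.at(s, v, wr)
        pool[r * n_nodes : (r + 1) * n_nodes] = s
    if total_accepted == 0:
        logger.warning(
            "all %d swap attempts rejected across %d replicates; null equals "
            "the observed strength multiset", n_swaps * n_replicates, n_replicates,
        )
    return pool


def empirical_p(observed: np.ndarray, null_pool: np.ndarray) -> np.ndarray:
    """Upper-tail empirical p with a pseudo-count: (1 + #{null >= x}) / (1 + N)."""
    null_sorted = np.sort(null_pool)
    n = len(null_sorted)
    n_ge = n - np.searchsorted(null_sorted, observed, side="left")
    return (1.0 + n_ge) / (1.0 + n)


def find_all_hubs(
    net: nx.Graph,
    n_null: int = HUB_N_NULL,
    fdr_cut: float = FDR_CUT,
    exclude: Iterable[str] | None = None,
    seed: int | np.random.Generator | None = None,
    shuffle_weights: bool = False,
) -> pd.DataFrame:
    """Hub significance for every gene of a CGN.

    Rewired replicates are accumulated until the pooled null holds at least
    ``n_null`` strength values; each gene's strength is ranked in the pool
    (pseudo-count empirical p), p-values are Benjamini-Hochberg adjusted
    across genes, and hubs are genes with FDR < ``fdr_cut`` that are not on
    the exclusion list (ribosomal proteins by default; pass ``exclude=()`` to
    disable).

    Returns a DataFrame indexed by gene with columns ``strength``,
    ``percentile_rank``, ``p_value``, ``fdr``, ``is_hub``, sorted by
    decreasing strength.
    """
    if net.number_of_edges() < 3:
        raise ValueError(
            "network too small to rewire: need at least 3 edges for "
            "degree-preserving double-edge swaps"
        )
    if n_null < 1000:
        raise ValueError(f"n_null must be >= 1000, got {n_null}")
    rng = np.random.default_rng(seed)

    strengths = weighted_degree(net)
    genes = sorted(strengths)
    obs = np.array([strengths[g] for g in genes])
    pool = _null_strength_pool(net, n_null, rng, shuffle_weights=shuffle_weights)
    pvals = empirical_p(obs, pool)
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")

    excluded = default_exclusion(genes) if exclude is None else set(exclude)
    pr = percentile_rank(strengths)
    table = pd.DataFrame(
        {
            "strength": obs,
            "percentile_rank": [pr[g] for g in genes],
            "p_value": pvals,
            "fdr": fdr,
            "is_hub": [(f < fdr_cut) and (g not in excluded) for g, f in zip(genes, fdr)],
        },
        index=pd.Index(genes, name="gene"),
    )
    return table.sort_values(["strength", "gene"], ascending=[False, True], kind="stable")
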