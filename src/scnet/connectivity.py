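"""Gene-set compactness: within-group connectivity vs a degree-matched null.

A gene set that functions in a given cell type tends to be wired together in
that cell type's network.  Compactness is quantified by the number of
network edges with both endpoints inside the set, compared with the same
count for random gene sets in which each real gene is replaced by a gene of
similar (+/- tolerance) unweighted degree — preserving the degree profile so
that significance reflects wiring, not hubness.  The empirical p-value is
the rank of the observed connectivity in the null distribution, with a
pseudo-count so p is never exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import networkx as nx

from .defaults import CONNECTIVITY_N_NULL, DEGREE_TOLERANCE

__all__ = [
    "GeneSet",
    "ConnectivityResult",
    "within_group_connectivity",
    "sample_degree_matched_set",
    "connectivity_test",
]


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (e.g. one GMT record)."""

    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    @classmethod
    def from_genes(cls, name: str, genes: Iterable[str], description: str = "") -> "GeneSet":
        return cls(name=name, members=frozenset(genes), description=description)


def within_group_connectivity(net: nx.Graph, genes: GeneSet | Iterable[str]) -> int:
    """Number of network edges with both endpoints in the gene set.

    Genes absent from the network are ignored.
    """
    members = genes.members if isinstance(genes, GeneSet) else set(genes)
    present = [g for g in members if g in net]
    return nx.induced_subgraph(net, present).number_of_edges()


def _degree_candidates(
    net: nx.Graph, tolerance: float
) -> tuple[list[str], np.ndarray, dict[int, np.ndarray]]:
    """Nodes sorted by degree and, per distinct degree, the candidate indices.

    Candidates for degree d are nodes with degree in
    [floor((1-tol)*d), ceil((1+tol)*d)] (bounds rounded outward).
    """
    nodes = sorted(net.nodes)
    degrees = np.array([net.degree(g) for g in nodes])
    order = np.argsort(degrees, kind="stable")
    sorted_nodes = [nodes[i] for i in order]
    sorted_deg = degrees[order]
    cands: dict[int, np.ndarray] = {}
    for d in np.unique(sorted_deg):
        lo = math.floor((1.0 - tolerance) * d)
        hi = math.ceil((1.0 + tolerance) * d)
        i0 = np.searchsorted(sorted_deg, lo, side="left")
        i1 = np.searchsorted(sorted_deg, hi, side="right")
        cands[int(d)] = np.arange(i0, i1)
    return sorted_nodes, sorted_deg, cands


def _pools_for(
    net: nx.Graph, present: Sequence[str], tolerance: float,
) -> tuple[list[str], list[np.ndarray]]:
    """Candidate index pools (one per real gene) over nodes sorted by degree."""
    sorted_nodes, _deg, cands = _degree_candidates(net, tolerance)
    pools = []
    for g in present:
        d = net.degree(g)
        pool = cands[int(d)]
        if len(pool) == 0:
            raise ValueError(
                f"gene {g!r} (degree {d}) has no degree-matched candidate "
                f"within tolerance {tolerance}"
            )
        pools.append(pool)
    return sorted_nodes, pools


def _draw_one_matched_row(
    pools: Sequence[np.ndarray],
    order: np.ndarray,
    rng: np.random.Generator,
    max_retries: int,
) -> list[int]:
    """One duplicate-free draw: per-gene rejection sampling without
    replacement, filling the most constrained (smallest) pools first."""
    k = len(pools)
    for _ in range(max_retries):
        chosen: dict[int, int] = {}
        taken: set[int] = set()
        for gi in order:
            pool = pools[gi]
            for _attempt in range(20):
                pick = int(pool[rng.integers(len(pool))])
                if pick not in taken:
                    break
            else:  # dense contention: enumerate what is left
                avail = [int(x) for x in pool if int(x) not in taken]
                if not avail:
                    break
                pick = avail[rng.integers(len(avail))]
            chosen[gi] = pick
            taken.add(pick)
        if len(chosen) == k:
            return [chosen[i] for i in range(k)]
    raise ValueError(
        f"could not draw a duplicate-free degree-matched set of size {k} "
        f"in {max_retries} attempts"
    )


def sample_degree_matched_set(
    net: nx.Graph,
    genes: GeneSet | Iterable[str],
    tolerance: float = DEGREE_TOLERANCE,
    seed: int | np.random.Generator | None = None,
    max_retries: int = 1000,
) -> list[str]:
    """One random gene set degree-matched to the real set.

    Each real gene (restricted to those present in the network) is replaced
    by a random network gene whose unweighted degree lies within
    +/- ``tolerance`` of the real gene's degree; genes are sampled without
    replacement within the returned set (per-gene rejection sampling).
    Raises ``ValueError`` (naming the gene and its degree) when a real gene
    has no candidate at all, or when no duplicate-free set can be completed
    in ``max_retries`` passes.  The i-th returned gene matches the i-th gene
    of the sorted present members.
    """
    rng = np.random.default_rng(seed)
    members = genes.members if isinstance(genes, GeneSet) else set(genes)
    present = sorted(g for g in members if g in net)
    sorted_nodes, pools = _pools_for(net, present, tolerance)
    order = np.argsort([len(p) for p in pools], kind="stable")
    row = _draw_one_matched_row(pools, order, rng, max_retries)
    return [sorted_nodes[i] for i in row]


@dataclass
class ConnectivityResult:
    """Outcome of one compactness test of a gene set against one network."""

    name: str
    n_in_network: int
    observed: float
    normalized: float | None
    null_samples: np.ndarray = field(repr=False)
    p_value: float | None
    evaluable: bool = True


def connectivity_test(
    net: nx.Graph,
    genes: GeneSet | Iterable[str],
    n_null: int = CONNECTIVITY_N_NULL,
    tolerance: float = DEGREE_TOLERANCE,
    seed: int | np.random.Generator | None = None,
    weighted: bool = False,
    max_retries: int = 1000,
) -> ConnectivityResult:
    """Compactness of a gene set: observed within-group connectivity vs null.

    ``n_null`` degree-matched random sets give the null distribution;
    p = (1 + #{null >= observed}) / (1 + n_null).  ``normalized`` is the
    observed connectivity divided by the number of set genes present in the
    network (so sets of different sizes are comparable across networks).
    With fewer than 2 set genes in the network the test is not evaluable:
    the result carries ``evaluable=False`` and ``p_value=None``.

    ``weighted=True`` sums edge weights instead of counting edges.
    """
    rng = np.random.default_rng(seed)
    gs = genes if isinstance(genes, GeneSet) else GeneSet.from_genes("geneset", genes)
    present = sorted(g for g in gs.members if g in net)
    k = len(present)
    if k < 2:
        return ConnectivityResult(
            name=gs.name, n_in_network=k, observed=0, normalized=None,
            null_samples=np.empty(0, dtype=int), p_value=None, evaluable=False,
        )

    sorted_nodes, pools = _pools_for(net, present, tolerance)
    node_index = {g: i for i, g in enumerate(sorted_nodes)}
    n = len(sorted_nodes)
    if weighted:
        adj = np.zeros((n, n))
        for a, b, w in net.edges(data="weight", default=1.0):
            adj[node_index[a], node_index[b]] = adj[node_index[b], node_index[a]] = w
    else:
        adj = np.zeros((n, n), dtype=bool)
        for a, b in net.edges:
            adj[node_index[a], node_index[b]] = adj[node_index[b], node_index[a]] = True

    idx = np.array([node_index[g] for g in present])
    observed = float(adj[np.ix_(idx, idx)].sum() / 2.0)
    if not weighted:
        observed = int(observed)

    # draw all null sets at once; rows with duplicates are rebuilt one by one
    # with per-gene sampling without replacement
    picks = np.column_stack([pool[rng.integers(len(pool), size=n_null)] for pool in pools])
    sorted_rows = np.sort(picks, axis=1)
    bad = (np.diff(sorted_rows, axis=1) == 0).any(axis=1)
    if bad.any():
        order = np.argsort([len(p) for p in pools], kind="stable")
        for row_idx in np.nonzero(bad)[0]:
            picks[row_idx] = _draw_one_matched_row(pools, order, rng, max_retries)

    null = np.empty(n_null, dtype=float if weighted else int)
    batch = max(1, int(2e7) // (k * k))  # bound peak memory of the gather
    for start in range(0, n_null, batch):
        block = picks[start : start + batch]
        sub = adj[block[:, :, None], block[:, None, :]]
        null[start : start + batch] = sub.sum(axis=(1, 2)) / 2.0

    p = float((1 + int((null >= observed).sum())) / (1 + n_null))
    return ConnectivityResult(
        name=gs.name,
        n_in_network=k,
        observed=observed,
        normalized=observed / k,
        null_samples=null,
        p_value=p,
        evaluable=True,
    )
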