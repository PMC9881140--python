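"""Weighted reference interactome and Bayesian log-likelihood link scoring.

The reference interactome is an undirected gene graph whose edge weights are
log-likelihood scores (LLS): for each link, the natural log of the ratio of
the posterior odds of functional linkage (given the supporting data) to the
prior odds derived from a gold standard.  Cell-type networks are always
subgraphs of this reference, and the same Bayesian machinery scores any
ranked link list against a gold standard, bin by bin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .defaults import LLS_BIN_SIZE

logger = logging.getLogger(__name__)

__all__ = [
    "canonical_pair",
    "load_interactome",
    "GoldStandard",
    "rank_links",
    "LLSBin",
    "compute_lls_curve",
]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered gene pair: (min, max) by string order."""
    return (a, b) if a <= b else (b, a)


def load_interactome(
    path: str | Path,
    min_weight: float | None = None,
    coding_genes: Iterable[str] | None = None,
    default_weight: float | None = None,
) -> nx.Graph:
    """Load a weighted edge-list TSV into an undirected reference graph.

    Parameters
    ----------
    path
        2- or 3-column TSV ``geneA<TAB>geneB[<TAB>weight]``. A header row is
        auto-detected (third field not parseable as a number).
    min_weight
        If given, edges with weight below this are dropped.
    coding_genes
        Optional protein-coding whitelist (e.g. CCDS symbols); edges with
        either endpoint outside it are dropped.
    default_weight
        Required for 2-column input; the weight assigned to every edge.

    Returns
    -------
    networkx.Graph with a positive ``weight`` attribute per edge.

    Raises
    ------
    ValueError
        On malformed rows (with the line number) or nonpositive weights.
        Self-loops are dropped with a warning, duplicates deduplicated.
    """
    coding = set(coding_genes) if coding_genes is not None else None
    graph = nx.Graph()
    n_self = n_dup = n_coding = n_light = 0
    first_data_row = True

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 2:
                if default_weight is None:
                    # maybe a header of a 3-col file gone wrong; treat as error
                    raise ValueError(
                        f"{path}: line {lineno}: 2-column row but no "
                        "default_weight supplied"
                    )
                a, b = fields
                w_str: str | None = None
            elif len(fields) >= 3:
                a, b, w_str = fields[0], fields[1], fields[2]
            else:
                raise ValueError(f"{path}: line {lineno}: expected 2 or 3 columns")

            if w_str is not None:
                try:
                    weight = float(w_str)
                except ValueError:
                    if first_data_row:  # header row auto-detected
                        first_data_row = False
                        continue
                    raise ValueError(
                        f"{path}: line {lineno}: weight {w_str!r} is not a number"
                    ) from None
            else:
                weight = float(default_weight)  # type: ignore[arg-type]
            first_data_row = False

            if weight <= 0:
                raise ValueError(
                    f"{path}: line {lineno}: nonpositive weight {weight}"
                )
            if a == b:
                n_self += 1
                continue
            if coding is not None and (a not in coding or b not in coding):
                n_coding += 1
                continue
            if min_weight is not None and weight < min_weight:
                n_light += 1
                continue
            u, v = canonical_pair(a, b)
            if graph.has_edge(u, v):
                n_dup += 1
                continue
            graph.add_edge(u, v, weight=weight)

    if n_self:
        logger.warning("%s: dropped %d self-loop record(s)", path, n_self)
    if n_dup:
        logger.info("%s: deduplicated %d repeated pair(s)", path, n_dup)
    if n_coding:
        logger.info("%s: dropped %d edge(s) outside the coding gene set", path, n_coding)
    if n_light:
        logger.info("%s: dropped %d edge(s) below min_weight", path, n_light)
    logger.info(
        "%s: loaded %d genes, %d edges", path, graph.number_of_nodes(),
        graph.number_of_edges(),
    )
    return graph


@dataclass(frozen=True)
class GoldStandard:
    """Gold-standard positive gene pairs over a fixed gene universe.

    Negatives are implicit: every pair over the universe not listed as a
    positive.  The prior P(L) is the fraction of positive pairs among all
    ``C(|universe|, 2)`` pairs.
    """

    positives: frozenset[tuple[str, str]]
    gene_universe: frozenset[str]

    def __post_init__(self) -> None:
        n = len(self.gene_universe)
        total = n * (n - 1) // 2
        if not self.positives:
            raise ValueError("gold standard has no positive pairs; prior undefined")
        if len(self.positives) >= total:
            raise ValueError("gold standard positives cover every pair; prior odds undefined")
        for a, b in self.positives:
            if a not in self.gene_universe or b not in self.gene_universe:
                raise ValueError(f"positive pair ({a}, {b}) outside the gene universe")
            if a > b:
                raise ValueError(f"positive pair ({a}, {b}) is not canonical (min, max)")
            if a == b:
                raise ValueError(f"self-pair ({a}, {a}) in positives")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]], universe: Iterable[str]) -> "GoldStandard":
        return cls(
            positives=frozenset(canonical_pair(a, b) for a, b in pairs),
            gene_universe=frozenset(universe),
        )

    @property
    def prior(self) -> float:
        """P(L): probability a random pair over the universe is a positive."""
        n = len(self.gene_universe)
        return len(self.positives) / (n * (n - 1) / 2)

    @property
    def prior_odds(self) -> float:
        """P(L) / P(not L)."""
        p = self.prior
        return p / (1.0 - p)


def rank_links(
    links: Iterable[tuple[str, str, float]],
) -> list[tuple[str, str, float]]:
    """Sort links by score descending; ties broken by canonical pair order.

    Pairs are canonicalized to (min, max); self-pairs are rejected.
    """
    out = []
    for a, b, score in links:
        if a == b:
            raise ValueError(f"self-pair ({a}, {a}) in ranked link list")
        u, v = canonical_pair(a, b)
        out.append((u, v, float(score)))
    out.sort(key=lambda t: (-t[2], t[0], t[1]))
    return out


@dataclass
class LLSBin:
    """One bin of an LLS curve.

    ``lls`` is ln((n_pos/n_neg) / prior_odds); it is +/-inf (and ``degenerate``
    is set) when a bin holds no negatives or no positives.
    """

    bin_index: int
    n_links: int
    n_pos: int
    n_neg: int
    lls: float
    degenerate: bool = field(default=False)


def compute_lls_curve(
    links: Sequence[tuple[str, str, float]],
    gold: GoldStandard,
    bin_size: int = LLS_BIN_SIZE,
) -> list[LLSBin]:
    """Score a ranked link list against a gold standard, bin by bin.

    Links are consumed in the given (descending-score) order.  Links with a
    gene outside ``gold.gene_universe`` are skipped entirely — counting them
    as negatives would bias the posterior downward.  Every ``bin_size``
    evaluable links form a bin with

        lls = ln( (n_pos / n_neg) / (P(L) / P(not L)) )

    The final partial bin is reported with its actual size.  A bin with zero
    positives or zero negatives gets -inf/+inf and is flagged ``degenerate``.
    """
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    prior_odds = gold.prior_odds
    universe = gold.gene_universe
    positives = gold.positives

    bins: list[LLSBin] = []
    n_pos = n_neg = 0

    def _close(index: int) -> None:
        n_links = n_pos + n_neg
        if n_pos == 0:
            lls, degen = -math.inf, True
        elif n_neg == 0:
            lls, degen = math.inf, True
        else:
            lls, degen = math.log((n_pos / n_neg) / prior_odds), False
        bins.append(LLSBin(index, n_links, n_pos, n_neg, lls, degen))

    for a, b, _score in links:
        if a == b:
            raise ValueError(f"self-pair ({a}, {a}) in ranked link list")
        u, v = canonical_pair(a, b)
        if u not in universe or v not in universe:
            continue
        if (u, v) in positives:
            n_pos += 1
        else:
            n_neg += 1
        if n_pos + n_neg == bin_size:
            _close(len(bins))
            n_pos = n_neg = 0

    if n_pos + n_neg:
        _close(len(bins))
    return bins
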