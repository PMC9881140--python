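"""Reference-guided construction of cell-type-specific gene networks (CGNs).

A CGN is the subgraph of the reference interactome induced by the genes that
are sufficiently *active* in one annotated cell population: a gene-pair link
is kept only when both genes pass the activity threshold for that population
AND the link exists in the reference.  Edge weights are always copied from
the reference (LLS), never re-estimated from the expression data.

The activity score is a deterministic, parameter-free stand-in for
archetype-based transforms: per cell, counts are library-size normalized
(counts per 10k), log1p-transformed, rank-transformed across genes (average
ranks for ties) and mapped through the standard normal quantile function;
per cell population the activity of a gene is the mean of its transformed
values over the population's cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import networkx as nx
from scipy import sparse, stats

from .defaults import MIN_CELLS, THRESHOLD, THRESHOLD_MODE

logger = logging.getLogger(__name__)

__all__ = [
    "compute_activity",
    "build_cgn",
    "build_all_cgns",
    "BuildSummary",
]

#: Scale factor for library-size normalization (counts per 10k).
NORM_TARGET = 1e4


def _transform_cells(counts: np.ndarray) -> np.ndarray:
    """Per-cell normalize/log1p/rank/inverse-normal transform.

    ``counts`` is cells x genes (dense, nonnegative).  Returns the same shape
    of standardized activity values.  All-zero cells transform to the value
    shared by all minimal ranks.
    """
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0  # all-zero cell: normalization is a no-op
    x = np.log1p(counts / lib * NORM_TARGET)
    ranks = stats.rankdata(x, method="average", axis=1)
    n_genes = counts.shape[1]
    return stats.norm.ppf((ranks - 0.5) / n_genes)


def compute_activity(
    adata,
    celltype_col: str = "cell_type",
    condition_col: str | None = None,
    min_cells: int = MIN_CELLS,
) -> pd.DataFrame:
    """Per-stratum gene activity from an annotated count matrix.

    Parameters
    ----------
    adata
        AnnData, cells x genes, raw nonnegative counts in ``X`` and the
        annotation column(s) in ``obs``.
    celltype_col, condition_col
        Strata are cell types, or (cell type, condition) pairs when a
        condition column is given.
    min_cells
        Strata with fewer cells are skipped with a warning.

    Returns
    -------
    DataFrame genes x strata of activity scores.  Columns are the cell-type
    label, or ``"{cell_type}|{condition}"`` for conditioned strata; the
    per-stratum cell counts are stored in ``df.attrs["n_cells"]``.
    """
    if celltype_col not in adata.obs:
        raise ValueError(f"annotation column {celltype_col!r} not found in obs")
    if condition_col is not None and condition_col not in adata.obs:
        raise ValueError(f"condition column {condition_col!r} not found in obs")

    if condition_col is None:
        strata = [(ct, None) for ct in sorted(map(str, adata.obs[celltype_col].unique()))]
    else:
        pairs = adata.obs[[celltype_col, condition_col]].astype(str)
        strata = sorted(set(map(tuple, pairs.itertuples(index=False))))

    columns: dict[str, np.ndarray] = {}
    n_cells: dict[str, int] = {}
    for cell_type, condition in strata:
        mask = adata.obs[celltype_col].astype(str) == cell_type
        if condition is not None:
            mask &= adata.obs[condition_col].astype(str) == condition
        n = int(mask.sum())
        label = cell_type if condition is None else f"{cell_type}|{condition}"
        if n < min_cells:
            logger.warning(
                "stratum %s has %d cells (< min_cells=%d); skipped", label, n, min_cells
            )
            continue
        X = adata.X[mask.values if hasattr(mask, "values") else mask]
        if sparse.issparse(X):
            X = X.toarray()
        if np.min(X) < 0:
            raise ValueError("count matrix has negative entries")
        columns[label] = _transform_cells(X).mean(axis=0)
        n_cells[label] = n

    activity = pd.DataFrame(columns, index=list(adata.var_names))
    activity.attrs["n_cells"] = n_cells
    return activity


def _activity_cutoff(col: pd.Series, threshold_mode: str, threshold: float) -> float:
    if threshold_mode == "percentile":
        if not 0 < threshold <= 1:
            raise ValueError(f"percentile threshold must be in (0, 1], got {threshold}")
        # threshold is the retained top fraction of genes
        return float(np.quantile(col.to_numpy(), 1.0 - threshold))
    if threshold_mode == "absolute":
        return float(threshold)
    raise ValueError(f"unknown threshold_mode {threshold_mode!r}")


def build_cgn(
    activity: pd.DataFrame,
    reference: nx.Graph,
    cell_type: str,
    threshold_mode: str = THRESHOLD_MODE,
    threshold: float = THRESHOLD,
) -> nx.Graph:
    """Build one CGN by thresholding a stratum's activity column.

    Genes with activity >= cutoff form the pass-set; the CGN is the
    reference subgraph induced on the pass-set, with reference edge weights.
    An empty pass-set yields an empty network with a warning.
    """
    if cell_type not in activity.columns:
        raise ValueError(f"no activity column for stratum {cell_type!r}")
    col = activity[cell_type]
    cutoff = _activity_cutoff(col, threshold_mode, threshold)
    passing = set(col.index[col.to_numpy() >= cutoff])
    if not passing:
        logger.warning("stratum %r: empty pass-set at cutoff %.4g", cell_type, cutoff)

    net = nx.Graph()
    for u, v, w in reference.edges(data="weight"):
        if u in passing and v in passing:
            net.add_edge(u, v, weight=w)
    net.graph.update(
        cell_type=cell_type,
        threshold_mode=threshold_mode,
        threshold=threshold,
        cutoff=cutoff,
        n_pass=len(passing),
    )
    # contract: a CGN is always a sub-network of the reference
    assert all(reference.has_edge(u, v) for u, v in net.edges)
    return net


@dataclass
class BuildSummary:
    """Per-stratum outcome of a batch CGN build."""

    stratum: str
    n_cells: int
    n_nodes: int
    n_edges: int
    status: str  # "built" or "skipped"


def build_all_cgns(
    adata,
    reference: nx.Graph,
    celltype_col: str = "cell_type",
    condition_col: str | None = None,
    threshold_mode: str = THRESHOLD_MODE,
    threshold: float = THRESHOLD,
    min_cells: int = MIN_CELLS,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, nx.Graph], list[BuildSummary]]:
    """Build one CGN per (cell type[, condition]) stratum.

    Strata below ``min_cells`` are skipped (listed in the summary) without
    aborting the batch.  When ``out_dir`` is given, each CGN is written as
    ``{stratum}.cgn.tsv`` plus a ``summary.tsv``.
    """
    from .io import save_network  # local import to avoid a cycle

    activity = compute_activity(
        adata, celltype_col=celltype_col, condition_col=condition_col,
        min_cells=min_cells,
    )
    n_cells: Mapping[str, int] = activity.attrs["n_cells"]

    # enumerate every stratum present in the annotation, built or not
    if condition_col is None:
        all_strata = sorted(map(str, adata.obs[celltype_col].unique()))
        counts = {s: int((adata.obs[celltype_col].astype(str) == s).sum()) for s in all_strata}
    else:
        pairs = adata.obs[[celltype_col, condition_col]].astype(str)
        tuples = sorted(set(map(tuple, pairs.itertuples(index=False))))
        all_strata = [f"{ct}|{cond}" for ct, cond in tuples]
        counts = {
            f"{ct}|{cond}": int(
                ((pairs[celltype_col] == ct) & (pairs[condition_col] == cond)).sum()
            )
            for ct, cond in tuples
        }

    networks: dict[str, nx.Graph] = {}
    summary: list[BuildSummary] = []
    for stratum in all_strata:
        if stratum not in activity.columns:
            summary.append(BuildSummary(stratum, counts[stratum], 0, 0, "skipped"))
            continue
        net = build_cgn(activity, reference, stratum, threshold_mode, threshold)
        if "|" in stratum:
            ct, cond = stratum.split("|", 1)
            net.graph["cell_type"], net.graph["condition"] = ct, cond
        networks[stratum] = net
        summary.append(
            BuildSummary(
                stratum, n_cells[stratum], net.number_of_nodes(),
                net.number_of_edges(), "built",
            )
        )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for stratum, net in networks.items():
            fname = stratum.replace("|", ".") + ".cgn.tsv"
            save_network(net, out_dir / fname)
        pd.DataFrame([vars(s) for s in summary]).to_csv(
            out_dir / "summary.tsv", sep="\t", index=False
        )
    return networks, summary
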