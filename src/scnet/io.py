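"""Readers and writers shared by all subcommands.

Formats: Matrix Market sparse triplets (1-based indices) with ``genes.tsv``
and ``cells.tsv`` sidecars, dense TSV count matrices, 3-column edge-list
TSVs for networks, and GMT for gene sets.  All writers are deterministic
(stable row ordering) and stamp a ``#`` comment header with the tool
version and the parameters/seed of the producing run.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import anndata as ad
import numpy as np
import pandas as pd
import networkx as nx
from scipy import io as spio
from scipy import sparse

from .connectivity import GeneSet
from .reference import canonical_pair

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "save_network",
    "load_network",
    "write_table",
]


def _header_lines(params: Mapping[str, object] | None) -> list[str]:
    from . import __version__

    lines = [f"# scnet v{__version__}"]
    if params:
        rendered = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
        lines.append(f"# {rendered}")
    return lines


def read_expression(
    counts_path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    celltype_col: str = "cell_type",
    condition_col: str | None = None,
) -> ad.AnnData:
    """Load a count matrix plus annotations into an AnnData (cells x genes).

    ``counts_path`` is either a Matrix Market ``.mtx`` file (genes x cells,
    1-based triplets) with mandatory ``genes.tsv``/``cells.tsv`` sidecars, or
    a dense TSV (gene rows, cell columns, gene ids in the first column).
    ``cells.tsv`` must contain ``cell_id`` and the cell-type column (plus the
    condition column when requested); dimension or column mismatches are
    hard errors.
    """
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        if genes_path is None or cells_path is None:
            raise ValueError(".mtx input requires genes and cells sidecar files")
        mat = spio.mmread(counts_path).tocsr()  # genes x cells
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
        cells = pd.read_csv(cells_path, sep="\t")
        if mat.shape[0] != len(genes):
            raise ValueError(
                f"matrix has {mat.shape[0]} gene rows but {genes_path} lists {len(genes)}"
            )
        if mat.shape[1] != len(cells):
            raise ValueError(
                f"matrix has {mat.shape[1]} cell columns but {cells_path} lists {len(cells)}"
            )
        X = mat.T.tocsr()
    else:
        dense = pd.read_csv(counts_path, sep="\t", index_col=0)
        genes = dense.index.astype(str).tolist()
        X = sparse.csr_matrix(dense.to_numpy(dtype=np.int64).T)
        if cells_path is None:
            raise ValueError("dense TSV input requires a cells annotation file")
        cells = pd.read_csv(cells_path, sep="\t")
        if len(cells) != X.shape[0]:
            raise ValueError(
                f"matrix has {X.shape[0]} cells but {cells_path} lists {len(cells)}"
            )

    for col in ["cell_id", celltype_col] + ([condition_col] if condition_col else []):
        if col not in cells.columns:
            raise ValueError(f"{cells_path}: required column {col!r} is missing")
    obs = cells.set_index("cell_id")
    obs.index = obs.index.astype(str)
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))


def write_expression(adata: ad.AnnData, out_dir: str | Path) -> None:
    """Write matrix.mtx (genes x cells) + genes.tsv + cells.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(np.asarray(X))
    spio.mmwrite(out_dir / "matrix.mtx", X.T.tocoo(), field="integer")
    (out_dir / "genes.tsv").write_text("".join(f"{g}\n" for g in adata.var_names))
    cells = adata.obs.reset_index(names="cell_id")
    cells.to_csv(out_dir / "cells.tsv", sep="\t", index=False)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one tab-separated ``name description member...`` per line."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT needs name, description and "
                    "at least one member"
                )
            name, description, members = fields[0], fields[1], fields[2:]
            sets.append(GeneSet.from_genes(name, [m for m in members if m], description))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.name}\t{gs.description}\t{members}\n")


def save_network(
    net: nx.Graph, path: str | Path, params: Mapping[str, object] | None = None
) -> None:
    """Write a network as a commented 3-column edge-list TSV.

    Rows are sorted by canonical pair so output is deterministic; network
    metadata (``net.graph``) and any extra ``params`` go into the header.
    """
    meta = dict(net.graph)
    if params:
        meta.update(params)
    rows = sorted(
        (canonical_pair(a, b) + (w,)) for a, b, w in net.edges(data="weight", default=1.0)
    )
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        fh.write("geneA\tgeneB\tweight\n")
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{w:.10g}\n")


def load_network(path: str | Path) -> nx.Graph:
    """Read an edge-list TSV written by :func:`save_network`."""
    from .reference import load_interactome

    return load_interactome(path)


def write_table(
    records: pd.DataFrame | Iterable, path: str | Path,
    params: Mapping[str, object] | None = None,
) -> None:
    """Write a results table as TSV with the standard comment header.

    ``records`` may be a DataFrame or an iterable of dataclass instances.
    """
    if not isinstance(records, pd.DataFrame):
        rows = []
        for r in records:
            if hasattr(r, "__dataclass_fields__"):
                rows.append({f: getattr(r, f) for f in r.__dataclass_fields__})
            else:
                rows.append(dict(r))
        records = pd.DataFrame(rows)
    with open(path, "w") as fh:
        for line in _header_lines(params):
            fh.write(line + "\n")
        records.to_csv(fh, sep="\t", index=records.index.name is not None)
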