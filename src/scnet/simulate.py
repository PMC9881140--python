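"""Synthetic fixtures: modular interactome + overdispersed zero-inflated counts.

The generator emulates the statistical structure the network statistics are
designed for, at desk scale:

* a sparse reference interactome containing dense functional modules
  (planted-partition graph, uniform stand-in LLS weights);
* a gold standard whose positives are the within-module gene pairs;
* single-cell counts that are negative-binomial with independent dropout
  zeros, where each annotated cell type over-expresses one planted module —
  so each cell type's network should recover its module.

A disease copy of a control network can be made by planting one additional
perturbed module (a disease-gained set of genes densely wired together),
and a counts-level perturbation by binomial thinning of one module's counts.
Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import networkx as nx

from .reference import GoldStandard, canonical_pair

__all__ = [
    "SimulationConfig",
    "make_reference",
    "make_gold_standard",
    "simulate_counts",
    "plant_disease_module",
    "knockdown_counts",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic benchmark.

    Defaults: a 300-gene interactome with six 20-gene modules (within-module
    edge probability 0.3 over a 0.01 background), three cell types of 200
    cells each over-expressing modules 1-3 at 4-fold, 50% dropout, and
    negative-binomial dispersion 0.5.
    """

    n_genes: int = 300
    n_modules: int = 6
    module_size: int = 20
    within_module_edge_prob: float = 0.3
    background_edge_prob: float = 0.01
    cell_types: tuple[tuple[str, int], ...] = (("CT1", 200), ("CT2", 200), ("CT3", 200))
    expression_effect: float = 4.0
    dropout_prob: float = 0.5
    nb_dispersion: float = 0.5
    baseline_log_mean: float = float(np.log(2.0))
    baseline_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("modules do not fit: n_modules * module_size > n_genes")
        for p in (self.within_module_edge_prob, self.background_edge_prob, self.dropout_prob):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.expression_effect < 1:
            raise ValueError("expression_effect must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if len(self.cell_types) > self.n_modules:
            raise ValueError("need at least one module per cell type")

    @property
    def gene_names(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]


def _module_map(cfg: SimulationConfig) -> dict[str, list[str]]:
    genes = cfg.gene_names
    return {
        f"M{m + 1}": genes[m * cfg.module_size : (m + 1) * cfg.module_size]
        for m in range(cfg.n_modules)
    }


def make_reference(
    cfg: SimulationConfig, seed: int | np.random.Generator | None = None
) -> tuple[nx.Graph, dict[str, list[str]]]:
    """Planted-partition reference interactome plus the module ground truth.

    Within-module pairs get an edge with probability
    ``within_module_edge_prob``, all other pairs with
    ``background_edge_prob``; weights are Uniform(1, 3) stand-in LLS values.
    Only genes with at least one edge appear as nodes.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    genes = cfg.gene_names
    modules = _module_map(cfg)
    module_of = np.full(cfg.n_genes, -1)
    for m in range(cfg.n_modules):
        module_of[m * cfg.module_size : (m + 1) * cfg.module_size] = m

    iu, ju = np.triu_indices(cfg.n_genes, k=1)
    same = (module_of[iu] >= 0) & (module_of[iu] == module_of[ju])
    prob = np.where(same, cfg.within_module_edge_prob, cfg.background_edge_prob)
    keep = rng.random(len(iu)) < prob
    weights = rng.uniform(1.0, 3.0, size=int(keep.sum()))

    graph = nx.Graph()
    for a, b, w in zip(iu[keep], ju[keep], weights):
        graph.add_edge(genes[a], genes[b], weight=float(w))
    return graph, modules


def make_gold_standard(
    modules: dict[str, Sequence[str]], universe: Sequence[str]
) -> GoldStandard:
    """Gold standard: positives are all within-module pairs over the universe."""
    positives = {
        canonical_pair(a, b)
        for members in modules.values()
        for i, a in enumerate(members)
        for b in list(members)[i + 1 :]
    }
    if not positives:
        raise ValueError("no within-module pairs; gold-standard prior undefined")
    return GoldStandard(frozenset(positives), frozenset(universe))


def simulate_counts(
    cfg: SimulationConfig,
    modules: dict[str, Sequence[str]] | None = None,
    seed: int | np.random.Generator | None = None,
) -> ad.AnnData:
    """Annotated counts: NB noise, dropout, one over-expressed module per type.

    Cell type ``i`` over-expresses module ``i`` (in config order) at
    ``expression_effect``-fold.  Counts are negative binomial with
    gene-specific lognormal baseline means and variance
    ``mu + dispersion * mu^2``, then zeroed independently with
    ``dropout_prob``.  Returns an AnnData (cells x genes) with a
    ``cell_type`` annotation column.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    genes = cfg.gene_names
    modules = _module_map(cfg) if modules is None else modules
    module_names = list(modules)
    gene_index = {g: i for i, g in enumerate(genes)}

    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=cfg.n_genes)
    n_cells_total = sum(n for _, n in cfg.cell_types)
    counts = np.empty((n_cells_total, cfg.n_genes), dtype=np.int64)
    labels: list[str] = []
    row = 0
    r = 1.0 / cfg.nb_dispersion  # NB size parameter
    for i, (name, n_cells) in enumerate(cfg.cell_types):
        mu = baseline.copy()
        planted = modules[module_names[i]]
        mu[[gene_index[g] for g in planted]] *= cfg.expression_effect
        lam = rng.gamma(shape=r, scale=mu / r, size=(n_cells, cfg.n_genes))
        block = rng.poisson(lam)
        if cfg.dropout_prob > 0:
            block[rng.random(block.shape) < cfg.dropout_prob] = 0
        counts[row : row + n_cells] = block
        labels.extend([name] * n_cells)
        row += n_cells

    obs = pd.DataFrame(
        {"cell_type": labels},
        index=[f"cell{i + 1:05d}" for i in range(n_cells_total)],
    )
    adata = ad.AnnData(X=counts, obs=obs, var=pd.DataFrame(index=genes))
    adata.uns["planted_module"] = {
        name: module_names[i] for i, (name, _) in enumerate(cfg.cell_types)
    }
    return adata


def plant_disease_module(
    control: nx.Graph,
    module_size: int = 20,
    within_module_edge_prob: float = 0.3,
    attach_prob: float = 0.01,
    seed: int | np.random.Generator | None = None,
    prefix: str = "DIS",
) -> tuple[nx.Graph, list[str]]:
    """Disease copy of a control network: plant one perturbed (gained) module.

    ``module_size`` new genes are added, wired among themselves with
    ``within_module_edge_prob`` and to existing genes with ``attach_prob``;
    new edges get Uniform(1, 3) weights.  Models a disease-specific
    functional module absent from the control condition.
    """
    rng = np.random.default_rng(seed)
    disease = control.copy()
    new_genes = [f"{prefix}{i + 1:03d}" for i in range(module_size)]
    existing = sorted(control.nodes)
    for i, a in enumerate(new_genes):
        for b in new_genes[i + 1 :]:
            if rng.random() < within_module_edge_prob:
                disease.add_edge(a, b, weight=float(rng.uniform(1.0, 3.0)))
        for b in existing:
            if rng.random() < attach_prob:
                disease.add_edge(a, b, weight=float(rng.uniform(1.0, 3.0)))
    return disease, new_genes


def knockdown_counts(
    adata: ad.AnnData,
    genes: Sequence[str],
    factor: float = 4.0,
    seed: int | np.random.Generator | None = None,
) -> ad.AnnData:
    """Counts-level perturbation: binomial thinning of the given genes.

    Each count of a targeted gene is replaced by a Binomial(count, 1/factor)
    draw, emulating a ``factor``-fold knockdown while leaving every other
    gene untouched.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    rng = np.random.default_rng(seed)
    out = adata.copy()
    idx = [list(adata.var_names).index(g) for g in genes]
    X = np.asarray(out.X)
    X[:, idx] = rng.binomial(X[:, idx], 1.0 / factor)
    out.X = X
    return out
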