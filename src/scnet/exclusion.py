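"""Gene exclusion lists for hub calling.

The default list excludes ribosomal proteins (RPL*/RPS*/MRPL*/MRPS* symbol
prefixes, bundled in ``data/ribosomal_prefixes.txt``); interactomes are
biased toward the ribosome complex, so these genes would otherwise dominate
every hub list.  Users may override with an explicit gene list file.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

__all__ = ["ribosomal_prefixes", "default_exclusion", "load_exclusion_list"]


def ribosomal_prefixes() -> list[str]:
    """The bundled ribosomal gene-symbol prefixes."""
    text = resources.files("scnet.data").joinpath("ribosomal_prefixes.txt").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]

def default_exclusion(genes: Iterable[str]) -> set[str]:
    """Subset of ``genes`` matching the bundled ribosomal prefixes."""
    prefixes = tuple(ribosomal_prefixes())
    return {g for g in genes if g.startswith(prefixes)}


def load_exclusion_list(path: str | Path, universe: Iterable[str] | None = None) -> set[str]:
    """Read a plain-text gene list (one symbol per line, ``#`` comments).

    Genes absent from ``universe`` (when given) trigger a warning only.
    """
    genes = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                genes.add(g)
    if universe is not None:
        missing = genes - set(universe)
        if missing:
            logger.warning(
                "%s: %d excluded gene(s) not in the network universe (e.g. %s)",
                path, len(missing), sorted(missing)[0],
            )
    return genes
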