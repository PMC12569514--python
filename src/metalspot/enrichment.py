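"""Gene-set over-representation analysis (ORA).

A hypergeometric upper-tail test of overlap between a query list (e.g. the
top metal-correlated genes) and each set of a GMT collection, against the
universe of genes actually tested in the correlation screen.  One-sided
enrichment only; Benjamini-Hochberg adjustment across the sets of a
collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    name: str
    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        for set_name, genes in self.sets.items():
            if len(genes) < 1:
                raise ValueError(f"gene set {set_name!r} is empty")


def _normalize_genes(genes: list[str]) -> list[str]:
    """Uppercase and deduplicate, preserving first-seen order."""
    seen: dict[str, None] = {}
    for g in genes:
        g = g.strip().upper()
        if g:
            seen.setdefault(g, None)
    return list(seen)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per tab-separated line
    ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed GMT line (needs >= 3 fields)")
            name, desc, *genes = fields
            genes = _normalize_genes(genes)
            if not genes:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = genes
            descriptions[name] = desc
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return GeneSetCollection(path.stem, sets, descriptions, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")
    return path


def ora(
    query: list[str],
    universe: list[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    With N = |universe|, m = |set ∩ universe|, q = |query| and k the overlap,
    p_raw = P(X >= k) for X ~ Hypergeom(N, m, q).  Query genes outside the
    universe are dropped with a warning.  Returns one row per set sorted by
    p_raw, with BH-adjusted p across the collection.
    """
    uni = set(_normalize_genes(universe))
    qry = _normalize_genes(query)
    if not qry:
        raise ValueError("empty query gene list")
    dropped = [g for g in qry if g not in uni]
    if dropped:
        logger.warning("dropping %d query genes outside the universe", len(dropped))
    qset = set(qry) & uni
    if not qset:
        raise ValueError("no query gene is in the universe")

    N, q = len(uni), len(qset)
    rows = []
    for set_name, genes in collection.sets.items():
        members = set(_normalize_genes(genes)) & uni
        m = len(members)
        overlap = sorted(qset & members)
        k = len(overlap)
        p_raw = float(hypergeom.sf(k - 1, N, m, q)) if m > 0 else 1.0
        rows.append(
            {
                "set": set_name,
                "overlap": k,
                "query_size": q,
                "set_size": m,
                "universe_size": N,
                "p_raw": min(p_raw, 1.0),
                "genes": ";".join(overlap),
            }
        )
    result = pd.DataFrame(rows)
    result["p_bh"] = multipletests(result["p_raw"].to_numpy(), method="fdr_bh")[1]
    result = result.sort_values(
        by=["p_raw", "set"], ascending=True, kind="mergesort"
    ).reset_index(drop=True)
    return result[
        ["set", "overlap", "query_size", "set_size", "universe_size", "p_raw", "p_bh", "genes"]
    ]
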