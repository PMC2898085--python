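"""Generic over-representation analysis over gene-set collections.

A flat per-term screen: one-sided Fisher (hypergeometric upper tail)
and fold enrichment of a query gene list against each set in a
collection, filtered to terms hit by at least ``min_k`` query genes,
with Benjamini-Hochberg adjustment across the collection.  Also
provides tiered cell-type labeling from a fold-enrichment table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .discover import adjust_bh

logger = logging.getLogger(__name__)

DEFAULT_MIN_K = 3
DEFAULT_ALPHA = 0.05
CELL_TYPE_TIERS = (2.0, 5.0, 20.0)


@dataclass
class GeneSetCollection:
    """Named gene sets over a background universe."""

    name: str
    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        self.universe = set(self.universe)
        restricted = {}
        for term, genes in self.sets.items():
            genes = set(genes) & self.universe
            if genes:
                restricted[term] = genes
        dropped = len(self.sets) - len(restricted)
        if dropped:
            logger.warning("%d empty sets dropped after universe restriction",
                           dropped)
        self.sets = restricted

    @classmethod
    def from_gmt(cls, path: str | Path, universe: Iterable[str] | None = None,
                 name: str | None = None) -> "GeneSetCollection":
        sets: dict[str, set[str]] = {}
        genes_seen: set[str] = set()
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            term, _desc, *genes = line.rstrip("\n").split("\t")
            sets[term] = set(genes)
            genes_seen |= sets[term]
        uni = set(universe) if universe is not None else genes_seen
        return cls(name=name or Path(path).stem, sets=sets, universe=uni)

    def to_gmt(self, path: str | Path,
               descriptions: Mapping[str, str] | None = None) -> None:
        lines = []
        for term, genes in self.sets.items():
            desc = (descriptions or {}).get(term, "na")
            lines.append("\t".join([term, desc] + sorted(genes)))
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class EnrichmentResult:
    term: str
    k: int        # query genes in the set
    n: int        # query size after universe restriction
    K: int        # set size
    N: int        # universe size
    fold: float   # (k/n) / (K/N); 0 when k == 0
    p: float      # one-sided Fisher / hypergeometric upper tail
    q: float = np.nan


def ora(query: Iterable[str], gene_set: Iterable[str],
        universe: Iterable[str], term: str = "") -> EnrichmentResult:
    """One-sided over-representation test of ``query`` in ``gene_set``.

    Query genes outside the universe are dropped with a warning; the
    p-value is the hypergeometric probability of observing at least k
    of n query genes in a set of K within a universe of N.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query)
    outside = q - uni
    if outside:
        logger.warning("%d query genes outside the universe dropped",
                       len(outside))
        q &= uni
    s = set(gene_set) & uni
    k, n, K, N = len(q & s), len(q), len(s), len(uni)
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n and K else 1.0
    fold = (k / n) / (K / N) if k > 0 else 0.0
    return EnrichmentResult(term=term, k=k, n=n, K=K, N=N, fold=fold, p=p)


def screen_collection(query: Iterable[str], collection: GeneSetCollection,
                      min_k: int = DEFAULT_MIN_K,
                      alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Test every set; keep terms with k >= min_k; BH across the collection.

    All sets are tested (the BH family is the whole collection); the
    ``min_k`` and ``alpha`` filters are applied to the reported rows.
    Rows are sorted by p ascending.
    """
    results = [ora(query, genes, collection.universe, term=term)
               for term, genes in collection.sets.items()]
    if not results:
        return pd.DataFrame(columns=["term", "k", "n", "K", "N",
                                     "fold", "p", "q"])
    qvals = adjust_bh(np.array([r.p for r in results]))
    for r, qv in zip(results, qvals):
        r.q = float(qv)
    rows = [r.__dict__ for r in results
            if r.k >= min_k and r.p < alpha]
    out = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N",
                                      "fold", "p", "q"])
    return out.sort_values("p", ignore_index=True)


def cell_type_annotate(gene: str,
                       enrichment_table: Mapping[str, Mapping[str, float]],
                       thresholds: Iterable[float] = CELL_TYPE_TIERS,
                       ) -> dict[str, float]:
    """Tiered cell-type labels for a gene from a fold-enrichment table.

    ``enrichment_table`` maps gene -> {cell type: fold}.  The gene is
    labeled with each cell type whose fold passes the lowest threshold,
    with tier = highest threshold passed (thresholds inclusive).
    Absent genes yield an empty label set.
    """
    thresholds = sorted(thresholds)
    folds = enrichment_table.get(gene, {})
    labels = {}
    for cell_type, fold in folds.items():
        passed = [t for t in thresholds if fold >= t]
        if passed:
            labels[cell_type] = passed[-1]
    return labels
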