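"""Pattern-phenotype correlation and regulatory-network assembly.

Pattern activation summarizes a pattern's saline-referenced profile per
drug (summed over time points, for correlation with conditioned place
preference) or per drug x time point (for correlation with locomotor
activation).  The regulatory network combines three evidence layers
over shared gene IDs: gene-gene co-expression edges where the Pearson
correlation of profiles exceeds r_min (strict), TF-to-gene edges where
a conserved binding site of the TF's matrix lies in the gene's
promoter, and signaling-to-pattern edges where a pharmacological
dissection experiment is significant at p < p_max.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .dissect import DissectionResult
from .tfbs import TfbsHit

DEFAULT_R_MIN = 0.6
DEFAULT_P_MAX = 0.1


def pattern_activation(profiles: pd.DataFrame, pattern_genes: list[str],
                       mode: str = "per_time") -> pd.Series | pd.DataFrame:
    """Mean profile of a pattern's genes, summarized per drug (x time).

    ``per_time`` returns a drug x time table; ``summed`` returns one
    value per drug, the sum of the per-time values over time points.
    """
    if not pattern_genes:
        raise ValueError("pattern is empty")
    mean_profile = profiles.loc[pattern_genes].mean(axis=0)
    table = mean_profile.unstack("time_h")
    if mode == "per_time":
        return table
    if mode == "summed":
        return table.sum(axis=1)
    raise ValueError(f"unknown mode {mode!r}")


def correlate(x: Iterable[float], y: Iterable[float],
              method: str = "pearson") -> tuple[float, float]:
    """Correlation and two-sided p-value (Pearson or Spearman)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def build_network(profiles: pd.DataFrame,
                  pattern_membership: Mapping[str, str],
                  tfbs_hits: Iterable[TfbsHit] = (),
                  dissection_results: Iterable[DissectionResult] = (),
                  r_min: float = DEFAULT_R_MIN,
                  p_max: float = DEFAULT_P_MAX) -> nx.DiGraph:
    """Assemble the typed regulatory network.

    Nodes: pattern genes (node type ``gene`` with a ``pattern``
    attribute), transcription factors (``tf``, from hit matrix IDs) and
    signaling elements (``signaling``, from dissection experiment IDs).
    Edges: ``coexpression`` (gene-gene, Pearson r of profiles > r_min,
    strict), ``tfbs`` (TF -> gene, conserved hit present) and
    ``pharmacological`` (signaling -> pattern genes, dissection
    p < p_max).  No self-edges.
    """
    g = nx.DiGraph()
    genes = [gene for gene in profiles.index if gene in pattern_membership]
    for gene in genes:
        g.add_node(gene, node_type="gene", pattern=pattern_membership[gene])

    X = profiles.loc[genes].to_numpy(dtype=float)
    if len(genes) >= 2:
        sd = X.std(axis=1)
        ok = sd > 0
        R = np.corrcoef(X)
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if ok[i] and ok[j] and R[i, j] > r_min:
                    g.add_edge(genes[i], genes[j], edge_type="coexpression",
                               r=float(R[i, j]))

    for hit in tfbs_hits:
        if not hit.conserved or hit.gene not in g:
            continue
        tf = hit.matrix_id
        if tf == hit.gene:
            continue
        g.add_node(tf, node_type="tf")
        g.add_edge(tf, hit.gene, edge_type="tfbs", matrix_id=hit.matrix_id)

    for res in dissection_results:
        if res.p >= p_max:
            continue
        src = res.experiment or "inhibitor"
        g.add_node(src, node_type="signaling")
        for gene in genes:
            if pattern_membership[gene] == res.pattern and gene != src:
                g.add_edge(src, gene, edge_type="pharmacological",
                           p=float(res.p), pattern=res.pattern)
    return g


def export_network(net: nx.DiGraph, path, fmt: str = "graphml") -> None:
    """Write the network: lossless GraphML or attribute-free SIF."""
    if fmt == "graphml":
        nx.write_graphml(net, path)
    elif fmt == "sif":
        lines = []
        for u, v, attrs in net.edges(data=True):
            lines.append(f"{u}\t{attrs.get('edge_type', 'edge')}\t{v}")
        for node in nx.isolates(net):
            lines.append(str(node))
        from pathlib import Path
        Path(path).write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_network(path) -> nx.DiGraph:
    return nx.read_graphml(path)
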