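"""Hierarchical pattern discovery and correlation-based extension.

Drug-responsive genes are summarized as saline-referenced profiles
(standardized group mean of each drug x time cell minus the
time-matched saline mean), clustered by average-linkage agglomeration
on Euclidean distances, and cut at a height h (or into k clusters)
into core patterns.  Each core pattern is then extended over the whole
transcriptome by Pearson correlation of every gene's profile with the
pattern centroid at a stringent significance level (default
p < 1e-10), so membership lists may overlap between patterns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .data import NAIVE, SALINE, ExpressionData

logger = logging.getLogger(__name__)

DEFAULT_CUT_HEIGHT = 13.0
DEFAULT_EXTENSION_ALPHA = 1e-10


def build_profiles(data: ExpressionData,
                   genes: list[str] | None = None) -> pd.DataFrame:
    """Saline-referenced drug x time profiles of (a subset of) genes.

    For each drug and time point: mean over that cell's arrays minus
    the mean over time-matched saline arrays.  Naive arrays are
    excluded.  Columns are a (drug, time_h) MultiIndex in sorted order.
    """
    sheet = data.samples
    keep = (sheet["drug"] != NAIVE) & (sheet["arm"] != "naive")
    sheet = sheet[keep]
    X = data.values if genes is None else data.values.loc[genes]
    drugs = sorted(d for d in sheet["drug"].unique() if d != SALINE)
    times = sorted(sheet["time_h"].unique())
    cols = {}
    for t in times:
        sal = sheet[(sheet.drug == SALINE) & (sheet.time_h == t)]["sample_id"]
        sal_mean = X[list(sal)].mean(axis=1)
        for d in drugs:
            cell = sheet[(sheet.drug == d) & (sheet.time_h == t)]["sample_id"]
            cols[(d, t)] = X[list(cell)].mean(axis=1) - sal_mean
    profiles = pd.DataFrame(cols)
    profiles.columns = pd.MultiIndex.from_tuples(profiles.columns,
                                                names=["drug", "time_h"])
    return profiles.sort_index(axis=1)


@dataclass
class PatternSet:
    """Dendrogram, core clusters and (optionally) extended memberships."""

    linkage: np.ndarray                   # scipy linkage matrix
    genes: list[str]                      # leaf order fed to the linkage
    cut_height: float | None
    core: dict[str, list[str]]            # label -> member genes (disjoint)
    centroids: dict[str, pd.Series] = field(default_factory=dict)
    extended: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return list(self.core)


def cluster_genes(profiles: pd.DataFrame, h: float | None = DEFAULT_CUT_HEIGHT,
                  k: int | None = None, min_cluster_size: int = 1,
                  linkage_method: str = "average",
                  metric: str = "euclidean") -> PatternSet:
    """Agglomerative clustering of gene profiles, cut at height h or into k.

    Genes are put in lexicographic order before linkage so the result
    is independent of input order; clusters are the connected
    components below the cut and are labeled C1, C2, ... by decreasing
    size (ties by smallest member ID).

    With a ``k`` cut and ``min_cluster_size`` > 1, the cut is deepened
    until ``k`` clusters of at least that size exist, so isolated
    outlier profiles cannot absorb a cluster slot; the outliers are
    still reported as additional (small) clusters.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 genes to cluster")
    if k is None and (h is None or h <= 0):
        raise ValueError("cut height must be positive (or give k)")
    profiles = profiles.sort_index()
    genes = list(profiles.index)
    Z = hierarchy.linkage(pdist(profiles.to_numpy(), metric=metric),
                          method=linkage_method)
    if k is not None:
        flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        if min_cluster_size > 1:
            for k2 in range(k, min(len(genes), k + 10) + 1):
                flat = hierarchy.fcluster(Z, t=k2, criterion="maxclust")
                sizes = np.bincount(flat)
                if (sizes >= min_cluster_size).sum() >= k:
                    break
    else:
        flat = hierarchy.fcluster(Z, t=h, criterion="distance")
    groups: dict[int, list[str]] = {}
    for gene, c in zip(genes, flat):
        groups.setdefault(int(c), []).append(gene)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    core = {f"C{i + 1}": sorted(members) for i, members in enumerate(ordered)}
    ps = PatternSet(linkage=Z, genes=genes,
                    cut_height=h if k is None else None, core=core)
    for label, members in core.items():
        ps.centroids[label] = centroid(members, profiles)
    return ps


def centroid(cluster_genes_: list[str], profiles: pd.DataFrame) -> pd.Series:
    """Columnwise mean profile of a cluster (the least-squares center)."""
    if not cluster_genes_:
        raise ValueError("empty cluster")
    return profiles.loc[cluster_genes_].mean(axis=0)


def critical_r(n: int, alpha: float) -> float:
    """Smallest |r| significant at two-sided level alpha with n points."""
    if n < 4:
        raise ValueError("need at least 4 points")
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(t_crit / np.sqrt(t_crit ** 2 + n - 2))


def extend_pattern(centroid_profile: pd.Series, profiles: pd.DataFrame,
                   alpha: float = DEFAULT_EXTENSION_ALPHA) -> pd.DataFrame:
    """Genes whose profile correlates with the centroid at p < alpha.

    Pearson r against the centroid for every gene; two-sided p from
    t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.  Returns a
    DataFrame (gene, r, p) sorted by r descending.  Zero-variance
    profiles are excluded with a warning.
    """
    n = profiles.shape[1]
    if n < 4:
        raise ValueError("profiles must have at least 4 columns")
    X = profiles.to_numpy(dtype=float)
    c = centroid_profile.to_numpy(dtype=float)
    if c.std() == 0:
        raise ValueError("zero-variance centroid")
    Xc = X - X.mean(axis=1, keepdims=True)
    cc = c - c.mean()
    x_sd = np.sqrt((Xc ** 2).sum(axis=1))
    keep = x_sd > 0
    if (~keep).any():
        logger.warning("%d zero-variance profiles excluded", int((~keep).sum()))
    r = np.full(X.shape[0], np.nan)
    r[keep] = (Xc[keep] @ cc) / (x_sd[keep] * np.sqrt((cc ** 2).sum()))
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    out = pd.DataFrame({"gene": profiles.index, "r": r, "p": p})[keep]
    out = out[out["p"] < alpha].sort_values("r", ascending=False)
    return out.reset_index(drop=True)


def extend_patterns(pattern_set: PatternSet, all_profiles: pd.DataFrame,
                    alpha: float = DEFAULT_EXTENSION_ALPHA) -> PatternSet:
    """Fill ``pattern_set.extended`` for every core cluster."""
    for label, members in pattern_set.core.items():
        c = pattern_set.centroids.get(label)
        if c is None:
            c = centroid(members, all_profiles.loc[members])
        pattern_set.extended[label] = extend_pattern(c, all_profiles, alpha)
    return pattern_set


def overlap_report(members_a: list[str], members_b: list[str]) -> dict:
    """Overlap of two membership lists, as a percent of the smaller list.

    The denominator convention is recorded in the output so it is never
    implicit.
    """
    if not members_a or not members_b:
        raise ValueError("membership lists must be nonempty")
    A, B = set(members_a), set(members_b)
    inter = len(A & B)
    denom = min(len(A), len(B))
    return {
        "intersection": inter,
        "size_a": len(A),
        "size_b": len(B),
        "denominator": "smaller_list",
        "denominator_size": denom,
        "percent": 100.0 * inter / denom,
    }


def to_newick(pattern_set: PatternSet) -> str:
    """Dendrogram in Newick form, branch lengths from merge heights."""
    Z = pattern_set.linkage
    labels = pattern_set.genes
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def render(node: int) -> str:
        if node < n:
            return labels[node]
        left, right, height = int(Z[node - n, 0]), int(Z[node - n, 1]), Z[node - n, 2]
        parts = []
        for child in (left, right):
            parts.append(f"{render(child)}:{height - heights[child]:.6g}")
        heights[node] = height
        return "(" + ",".join(parts) + ")"

    # fill heights bottom-up before rendering branch lengths
    for i in range(Z.shape[0]):
        heights[n + i] = Z[i, 2]
    root = n + Z.shape[0] - 1
    return render(root) + ";"
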