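"""Normalization chain: quantile normalization, log2, batch z-scoring.

Also provides the qPCR relative-abundance transform (2**-Ct with a
reference-gene control) used when validating array results.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionData

logger = logging.getLogger(__name__)


def quantile_normalize(data: ExpressionData) -> ExpressionData:
    """Force every sample onto the common (row-mean) reference distribution.

    Each column's sorted values are replaced by the mean of the
    column-sorted matrix at that rank; ties within a column receive the
    mean of the reference values over their rank span.  Idempotent.
    """
    X = data.values.to_numpy(dtype=float)
    if X.size == 0:
        raise ValueError("empty matrix")
    order = np.argsort(X, axis=0, kind="stable")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        ranked = np.empty(X.shape[0])
        ranked[order[:, j]] = reference
        # average reference values over tied spans
        col = X[:, j]
        # rankdata('average') gives the mean rank of each tie group;
        # map it onto the reference by averaging the spanned entries
        uniq, inverse, counts = np.unique(col, return_inverse=True,
                                          return_counts=True)
        if len(uniq) != len(col):
            sorted_ref = reference  # reference is already rank-ordered
            csum = np.concatenate([[0.0], np.cumsum(sorted_ref)])
            starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
            tie_means = (csum[starts + counts] - csum[starts]) / counts
            out[:, j] = tie_means[inverse]
        else:
            out[:, j] = ranked
    values = pd.DataFrame(out, index=data.values.index,
                          columns=data.values.columns)
    return ExpressionData(values=values, samples=data.samples, log2=data.log2,
                          df_adjustment=data.df_adjustment)


def log2_transform(data: ExpressionData) -> ExpressionData:
    """Elementwise log2; raises naming the offending probe/sample."""
    X = data.values
    if (X <= 0).any().any():
        bad = X.le(0)
        probe = bad.any(axis=1).idxmax()
        sample = bad.loc[probe].idxmax()
        raise ValueError(
            f"nonpositive value at probe {probe!r}, sample {sample!r}")
    return ExpressionData(values=np.log2(X), samples=data.samples, log2=True,
                          df_adjustment=data.df_adjustment)


def standardize(data: ExpressionData, group_by: str = "batch",
                mode: str = "per_probe_within_batch") -> ExpressionData:
    """z-score transform removing hybridization-batch location/scale.

    ``per_probe_within_batch`` (default): per probe, within each batch,
    subtract the mean and divide by the standard deviation, which
    removes any per-batch additive or multiplicative distortion while
    preserving cross-group contrasts.  ``per_array`` z-scores each
    array (column) instead.  Constant probes map to 0 with a warning.

    Within-batch centering consumes one residual degree of freedom per
    probe per extra batch; the returned data records this in
    ``df_adjustment`` so the downstream ANOVA stays calibrated.
    """
    X = data.values.to_numpy(dtype=float)
    out = np.empty_like(X)
    if mode == "per_array":
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        out = (X - mu) / sd
    elif mode == "per_probe_within_batch":
        groups = data.samples.groupby(group_by)["sample_id"].apply(list)
        col_pos = {s: i for i, s in enumerate(data.values.columns)}
        n_constant = 0
        for _, sample_ids in groups.items():
            idx = [col_pos[s] for s in sample_ids]
            if len(idx) < 2:
                raise ValueError(f"batch with a single sample: {sample_ids}")
            block = X[:, idx]
            mu = block.mean(axis=1, keepdims=True)
            sd = block.std(axis=1, ddof=1, keepdims=True)
            constant = (sd == 0).ravel()
            n_constant += int(constant.sum())
            sd[sd == 0] = 1.0
            out[:, idx] = (block - mu) / sd
        if n_constant:
            logger.warning("%d constant probe/batch blocks mapped to 0",
                           n_constant)
    else:
        raise ValueError(f"unknown standardization mode {mode!r}")
    values = pd.DataFrame(out, index=data.values.index,
                          columns=data.values.columns)
    df_adj = data.df_adjustment
    if mode == "per_probe_within_batch":
        df_adj += data.samples[group_by].nunique() - 1
    return ExpressionData(values=values, samples=data.samples, log2=data.log2,
                          df_adjustment=df_adj)


def qpcr_relative_abundance(ct: float, ct_reference: float) -> dict[str, float]:
    """Abundance from threshold cycles: 2**-Ct, reference-normalized.

    Returns the raw abundance ``2**-ct`` and the reference-normalized
    ratio ``2**-(ct - ct_reference)``.
    """
    if not (np.isfinite(ct) and np.isfinite(ct_reference)):
        raise ValueError("cycle values must be finite")
    return {
        "abundance": 2.0 ** (-ct),
        "normalized_ratio": 2.0 ** (-(ct - ct_reference)),
    }


def qpcr_fold_change(ct_treated: float, ct_ref_treated: float,
                     ct_control: float, ct_ref_control: float) -> float:
    """Fold change over control by the delta-delta-Ct rule."""
    ddct = (ct_treated - ct_ref_treated) - (ct_control - ct_ref_control)
    return 2.0 ** (-ddct)
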