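"""Pharmacological dissection of drug-induced pattern activation.

An inhibitor (or receptor antagonist) given before the drug attenuates
the drug-induced transcriptional response of a pattern.  The effect is
summarized as a percent inhibition

    phi = (1 - a_i / a_d) * 100,

where a_d is the mean linear-scale activation of the pattern under
drug+vehicle (mean fold change over saline+vehicle, minus 1) and a_i
the activation under drug+inhibitor.  phi = 0 means no effect,
phi = 100 complete inhibition, phi > 100 suppression below the saline
baseline, and phi < 0 amplification.  Significance is a paired
two-tailed t-test across pattern genes of the two per-gene fold-change
vectors, and per-gene up/down "arrows" come from two-sample t-tests
between arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import SALINE, ExpressionData

DEFAULT_ACTIVATION_FLOOR = 0.1


@dataclass
class DissectionResult:
    experiment: str
    pattern: str
    fc_drug: pd.Series       # per-gene linear fold change, drug+vehicle
    fc_inhibitor: pd.Series  # per-gene linear fold change, drug+inhibitor
    activation_drug: float   # a_d = mean(FC_drug) - 1
    activation_inhibitor: float
    percent_inhibition: float | None
    p: float
    reliable: bool
    degenerate: bool = False


def _arm_columns(data: ExpressionData, drug: str, arm: str) -> list[str]:
    sheet = data.samples
    cols = sheet[(sheet.drug == drug) & (sheet.arm == arm)]["sample_id"].tolist()
    if len(cols) < 2:
        raise ValueError(f"arm ({drug!r}, {arm!r}) missing or has < 2 replicates")
    return cols


def fold_changes(data: ExpressionData, genes: list[str], drug: str,
                 arm: str) -> pd.Series:
    """Per-gene linear fold change of an arm over saline+vehicle.

    FC_g = 2**(mean log2 of the arm - mean log2 of saline+vehicle).
    """
    if not data.log2:
        raise ValueError("expression must be on the log2 scale")
    missing = [g for g in genes if g not in data.values.index]
    if missing:
        raise ValueError(f"pattern genes absent from matrix: {missing[:5]}")
    base_cols = _arm_columns(data, SALINE, "vehicle")
    arm_cols = _arm_columns(data, drug, arm)
    X = data.values.loc[genes]
    delta = X[arm_cols].mean(axis=1) - X[base_cols].mean(axis=1)
    return 2.0 ** delta


def percent_inhibition(data: ExpressionData, pattern_genes: list[str],
                       drug: str, pattern: str = "", experiment: str = "",
                       activation_floor: float = DEFAULT_ACTIVATION_FLOOR,
                       ) -> DissectionResult:
    """Percent inhibition of a pattern's drug response by the inhibitor arm.

    Requires saline+vehicle, drug+vehicle and drug+inhibitor arms with
    at least two replicates each.  phi is undefined (None) when the
    drug activation magnitude is negligible; results with |a_d| below
    ``activation_floor`` are flagged unreliable.
    """
    if not pattern_genes:
        raise ValueError("pattern is empty")
    fc_drug = fold_changes(data, pattern_genes, drug, "vehicle")
    fc_inh = fold_changes(data, pattern_genes, drug, "inhibitor")
    a_d = float(fc_drug.mean() - 1.0)
    a_i = float(fc_inh.mean() - 1.0)
    if abs(a_d) < 1e-12:
        phi = None
    else:
        phi = (1.0 - a_i / a_d) * 100.0
    p, degenerate = dissection_test(fc_drug, fc_inh)
    return DissectionResult(
        experiment=experiment, pattern=pattern,
        fc_drug=fc_drug, fc_inhibitor=fc_inh,
        activation_drug=a_d, activation_inhibitor=a_i,
        percent_inhibition=phi, p=p,
        reliable=abs(a_d) >= activation_floor,
        degenerate=degenerate,
    )


def dissection_test(fc_drug: pd.Series, fc_inhibitor: pd.Series,
                    ) -> tuple[float, bool]:
    """Paired two-tailed t-test across pattern genes of the two FC vectors.

    Returns (p, degenerate); all-zero differences give p = 1 with the
    degenerate flag set.
    """
    a = np.asarray(fc_drug, dtype=float)
    b = np.asarray(fc_inhibitor, dtype=float)
    if a.shape != b.shape:
        raise ValueError("fold-change vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pattern genes")
    diff = b - a
    if np.allclose(diff, 0.0) or diff.std(ddof=1) == 0.0:
        return 1.0, True
    t, p = stats.ttest_rel(b, a)
    return float(p), False


def per_gene_arrows(data: ExpressionData, genes: list[str],
                    arm_a: tuple[str, str], arm_b: tuple[str, str],
                    alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene direction of arm_a versus arm_b (two-sample t-test).

    ``arm_a``/``arm_b`` are (drug, arm) pairs.  Arrow is +1/-1 by the
    sign of the mean difference when p < alpha, else 0.
    """
    cols_a = _arm_columns(data, *arm_a)
    cols_b = _arm_columns(data, *arm_b)
    X = data.values.loc[genes]
    A = X[cols_a].to_numpy()
    B = X[cols_b].to_numpy()
    t, p = stats.ttest_ind(A, B, axis=1)
    diff = A.mean(axis=1) - B.mean(axis=1)
    arrow = np.where(p < alpha, np.sign(diff), 0.0).astype(int)
    return pd.DataFrame({"gene": genes, "diff": diff, "p": p, "arrow": arrow})


def dissection_table(results: list[DissectionResult]) -> pd.DataFrame:
    """Flat summary table (one row per experiment x pattern)."""
    rows = []
    for r in results:
        rows.append({
            "experiment": r.experiment, "pattern": r.pattern,
            "activation_drug": r.activation_drug,
            "activation_inhibitor": r.activation_inhibitor,
            "percent_inhibition": r.percent_inhibition,
            "p": r.p, "reliable": r.reliable, "degenerate": r.degenerate,
        })
    return pd.DataFrame(rows)
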