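"""Per-probe two-way ANOVA, multiple-testing control and post-hoc contrasts.

Every probe is tested with a drug x time two-way ANOVA (saline included
as a drug level, naive arrays excluded).  Raw p-values per factor are
adjusted by Bonferroni and by the Benjamini-Hochberg step-up, and a
true-positive curve TP(q) = N(q) * (1 - q/100) sizes the responsive
transcriptome across a grid of FDR levels.  Drug-versus-saline effects
at each time point are resolved with Tukey's honest significant
difference over the drug x time cell means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import NAIVE, SALINE, ExpressionData

_DEGENERATE_TOL = 1e-12


@dataclass
class AnovaResult:
    """Per-probe F/p table plus the fitted cell means for post-hoc tests."""

    table: pd.DataFrame            # indexed by probe
    cell_means: pd.DataFrame       # probes x (drug, time) MultiIndex columns
    cell_n: pd.Series              # samples per (drug, time) cell
    mse: pd.Series                 # residual mean square per probe
    df_resid: int
    factors: dict[str, int] = field(default_factory=dict)  # factor -> df


def _check_design(sheet: pd.DataFrame) -> pd.DataFrame:
    sheet = sheet[(sheet["drug"] != NAIVE) & (sheet["arm"] != "naive")]
    counts = sheet.groupby(["drug", "time_h"]).size()
    drugs = sheet["drug"].unique()
    times = sheet["time_h"].unique()
    if SALINE not in drugs:
        raise ValueError("design must include a saline level")
    missing = [(d, t) for d in drugs for t in times if (d, t) not in counts.index]
    if missing:
        raise ValueError(f"empty design cells: {missing}")
    if (counts < 2).any():
        thin = counts[counts < 2].index.tolist()
        raise ValueError(f"cells with fewer than 2 replicates: {thin}")
    return sheet


def fit_two_way_anova(data: ExpressionData,
                      include_interaction: bool = True) -> AnovaResult:
    """Drug x time ANOVA for every probe.

    Balanced designs use classical sums of squares (vectorized over
    probes); unbalanced designs fall back to per-probe Type II partial
    sums of squares via statsmodels.  Probes with zero total variance
    are flagged degenerate and reported with F = 0, p = 1.
    """
    sheet = _check_design(data.samples)
    Y = data.values[sheet["sample_id"].tolist()].to_numpy(dtype=float)
    drugs = sorted(sheet["drug"].unique())
    times = sorted(sheet["time_h"].unique())
    a, b = len(drugs), len(times)
    counts = sheet.groupby(["drug", "time_h"]).size()
    balanced = counts.nunique() == 1

    if balanced:
        res = _fit_balanced(Y, sheet, drugs, times, include_interaction,
                            data.df_adjustment)
    else:
        res = _fit_type2(Y, sheet, drugs, times, include_interaction)

    table, cell_means, mse, df_resid, dfs = res
    table.index = data.values.index
    cell_means.index = data.values.index
    mse.index = data.values.index

    m = len(table)
    for factor in ("drug", "time", "interaction"):
        pcol = f"p_{factor}"
        if pcol not in table:
            continue
        table[f"p_bonferroni_{factor}"] = adjust_bonferroni(table[pcol].to_numpy(), m)
        table[f"q_bh_{factor}"] = adjust_bh(table[pcol].to_numpy())
    return AnovaResult(table=table, cell_means=cell_means,
                       cell_n=counts, mse=mse, df_resid=df_resid, factors=dfs)


def _fit_balanced(Y, sheet, drugs, times, include_interaction,
                  df_adjustment=0):
    P, N = Y.shape
    drug_idx = sheet["drug"].map({d: i for i, d in enumerate(drugs)}).to_numpy()
    time_idx = sheet["time_h"].map({t: i for i, t in enumerate(times)}).to_numpy()
    a, b = len(drugs), len(times)
    n = N // (a * b)

    g = Y.mean(axis=1, keepdims=True)
    ss_tot = ((Y - g) ** 2).sum(axis=1)

    def level_means(idx, k):
        sums = np.zeros((P, k))
        for lv in range(k):
            sums[:, lv] = Y[:, idx == lv].sum(axis=1)
        return sums / np.bincount(idx, minlength=k)

    m_drug = level_means(drug_idx, a)
    m_time = level_means(time_idx, b)
    cell_idx = drug_idx * b + time_idx
    m_cell = level_means(cell_idx, a * b)

    ssa = (b * n) * ((m_drug - g) ** 2).sum(axis=1)
    ssb = (a * n) * ((m_time - g) ** 2).sum(axis=1)
    ss_cells = n * ((m_cell - g) ** 2).sum(axis=1)
    ssab = ss_cells - ssa - ssb
    sse = ss_tot - ss_cells

    df_a, df_b, df_ab = a - 1, b - 1, (a - 1) * (b - 1)
    if include_interaction:
        df_resid = N - a * b - df_adjustment
    else:
        sse = sse + ssab
        df_resid = N - a - b + 1 - df_adjustment

    mse = sse / df_resid
    degenerate = ss_tot < _DEGENERATE_TOL

    def f_and_p(ss, df):
        with np.errstate(divide="ignore", invalid="ignore"):
            F = np.where(mse > 0, (ss / df) / np.where(mse > 0, mse, 1.0), np.inf)
        F = np.where(degenerate, 0.0, F)
        p = np.where(degenerate, 1.0, stats.f.sf(F, df, df_resid))
        return F, p

    F_drug, p_drug = f_and_p(ssa, df_a)
    F_time, p_time = f_and_p(ssb, df_b)
    table = pd.DataFrame({
        "F_drug": F_drug, "p_drug": p_drug,
        "F_time": F_time, "p_time": p_time,
        "degenerate": degenerate,
    })
    dfs = {"drug": df_a, "time": df_b}
    if include_interaction:
        F_int, p_int = f_and_p(ssab, df_ab)
        table.insert(4, "F_interaction", F_int)
        table.insert(5, "p_interaction", p_int)
        dfs["interaction"] = df_ab

    cols = pd.MultiIndex.from_product([drugs, times], names=["drug", "time_h"])
    cell_means = pd.DataFrame(m_cell, columns=cols)
    return table, cell_means, pd.Series(mse), df_resid, dfs


def _fit_type2(Y, sheet, drugs, times, include_interaction):
    """Per-probe Type II ANOVA via statsmodels (unbalanced designs)."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    formula = ("y ~ C(drug) * C(time_h)" if include_interaction
               else "y ~ C(drug) + C(time_h)")
    frame = sheet[["drug", "time_h"]].copy().reset_index(drop=True)
    rows, mses = [], []
    cols = pd.MultiIndex.from_product([drugs, times], names=["drug", "time_h"])
    cell_rows = []
    df_resid = None
    dfs = {}
    for i in range(Y.shape[0]):
        frame["y"] = Y[i]
        if frame["y"].var() < _DEGENERATE_TOL:
            row = {"F_drug": 0.0, "p_drug": 1.0, "F_time": 0.0, "p_time": 1.0,
                   "degenerate": True}
            if include_interaction:
                row.update(F_interaction=0.0, p_interaction=1.0)
            rows.append(row)
            mses.append(0.0)
            grouped = frame.groupby(["drug", "time_h"])["y"].mean()
            cell_rows.append([grouped.get(c, np.nan) for c in cols])
            continue
        fit = smf.ols(formula, data=frame).fit()
        aov = sm.stats.anova_lm(fit, typ=2)
        row = {
            "F_drug": aov.loc["C(drug)", "F"],
            "p_drug": aov.loc["C(drug)", "PR(>F)"],
            "F_time": aov.loc["C(time_h)", "F"],
            "p_time": aov.loc["C(time_h)", "PR(>F)"],
            "degenerate": False,
        }
        dfs = {"drug": int(aov.loc["C(drug)", "df"]),
               "time": int(aov.loc["C(time_h)", "df"])}
        if include_interaction:
            row["F_interaction"] = aov.loc["C(drug):C(time_h)", "F"]
            row["p_interaction"] = aov.loc["C(drug):C(time_h)", "PR(>F)"]
            dfs["interaction"] = int(aov.loc["C(drug):C(time_h)", "df"])
        rows.append(row)
        df_resid = int(fit.df_resid)
        mses.append(fit.mse_resid)
        grouped = frame.groupby(["drug", "time_h"])["y"].mean()
        cell_rows.append([grouped.get(c, np.nan) for c in cols])
    table = pd.DataFrame(rows)
    cell_means = pd.DataFrame(cell_rows, columns=cols)
    return table, cell_means, pd.Series(mses), df_resid, dfs


# ---------------------------------------------------------------------------
# multiple-testing adjustment


def adjust_bonferroni(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni family-wise adjustment: min(1, p * m)."""
    p = np.asarray(p, dtype=float)
    if m is None:
        m = p.size
    if m <= 0:
        raise ValueError("m must be positive")
    if m < p.size:
        raise ValueError("m smaller than the number of p-values")
    return np.minimum(1.0, p * m)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold guaranteeing family-wise error alpha over m tests."""
    if m <= 0:
        raise ValueError("m must be positive")
    return alpha / m


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# true-positive curve


@dataclass
class TruePositiveCurve:
    """TP(q) over a grid of percent-FDR levels.

    ``curve`` has columns q_percent, N (discoveries at that BH level)
    and TP = round(N * (1 - q/100)).  ``plateau`` is the q-range over
    which TP stays within ``band`` (a fraction of the maximum) of the
    maximum.  ``plateau_tp`` is the median TP over the grid -- a robust
    estimate of the plateau height, since TP(q) at very loose FDR
    levels is a high-variance quantity (the BH rejection boundary
    crosses the p-value order statistics at a shallow angle there).
    """

    curve: pd.DataFrame
    argmax_q: float
    max_tp: int
    plateau: tuple[float, float]
    plateau_tp: int


def tp_curve(q_values: np.ndarray, grid: np.ndarray,
             band: float = 0.1) -> TruePositiveCurve:
    """Estimated true positives across percent-FDR levels.

    ``q_values`` are BH q-values in [0, 1]; ``grid`` is in percent.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    q_values = np.asarray(q_values, dtype=float)
    if ((q_values < 0) | (q_values > 1)).any():
        raise ValueError("q-values must lie in [0, 1]")
    N = np.array([(q_values <= q / 100.0).sum() for q in grid])
    TP = np.rint(N * (1.0 - grid / 100.0)).astype(int)
    curve = pd.DataFrame({"q_percent": grid, "N": N, "TP": TP})
    imax = int(TP.argmax())
    max_tp = int(TP[imax])
    near = grid[TP >= max_tp * (1.0 - band)]
    plateau = (float(near.min()), float(near.max())) if near.size else (
        float(grid[imax]), float(grid[imax]))
    return TruePositiveCurve(curve=curve, argmax_q=float(grid[imax]),
                             max_tp=max_tp, plateau=plateau,
                             plateau_tp=int(np.median(TP)))


# ---------------------------------------------------------------------------
# Tukey post-hoc contrasts


def tukey_critical_value(alpha: float, n_means: int, df: int) -> float:
    """Studentized-range critical value q_{alpha}(k, df)."""
    return float(stats.studentized_range.ppf(1.0 - alpha, n_means, df))


def tukey_drug_vs_saline(anova: AnovaResult, alpha: float = 0.05,
                         compute_p: bool = False) -> pd.DataFrame:
    """Tukey HSD contrasts of each drug against time-matched saline.

    The family is all drug x time cell means of the fitted ANOVA; only
    drug-versus-saline contrasts at matching time points are reported.
    Returns a long table (probe, drug, time_h, diff, q_stat,
    significant, direction) where direction is the sign of
    drug minus saline.
    """
    cols = anova.cell_means.columns
    drugs = [d for d in cols.get_level_values("drug").unique() if d != SALINE]
    times = cols.get_level_values("time_h").unique()
    if SALINE not in cols.get_level_values("drug"):
        raise ValueError("no saline cells in the fitted design")
    k = len(cols)
    q_crit = tukey_critical_value(alpha, k, anova.df_resid)

    frames = []
    mse = anova.mse.to_numpy()
    for d in drugs:
        for t in times:
            n1 = anova.cell_n[(d, t)]
            n0 = anova.cell_n[(SALINE, t)]
            diff = (anova.cell_means[(d, t)] - anova.cell_means[(SALINE, t)]
                    ).to_numpy()
            # Tukey-Kramer standard error of a pairwise contrast
            se = np.sqrt(mse / 2.0 * (1.0 / n1 + 1.0 / n0))
            with np.errstate(divide="ignore", invalid="ignore"):
                q_stat = np.where(se > 0, np.abs(diff) / se, 0.0)
            frame = pd.DataFrame({
                "probe": anova.cell_means.index,
                "drug": d, "time_h": t, "diff": diff, "q_stat": q_stat,
                "significant": q_stat > q_crit,
                "direction": np.sign(diff).astype(int),
            })
            if compute_p:
                frame["p"] = stats.studentized_range.sf(
                    q_stat, k, anova.df_resid)
            frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    out.loc[~out["significant"], "direction"] = 0
    return out
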