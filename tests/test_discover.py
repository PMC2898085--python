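import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import stridemod as sm
from stridemod.config import SimulationConfig
from stridemod.data import ExpressionData
from stridemod.discover import (adjust_bh, adjust_bonferroni,
                                bonferroni_threshold, fit_two_way_anova,
                                tp_curve, tukey_critical_value,
                                tukey_drug_vs_saline)


def design_data(cell_means: dict, n_rep: int = 3, noise=None, seed=0):
    """Build an ExpressionData from per-(drug, time) cell means for one probe.

    ``cell_means`` maps (drug, time) -> list of probe means.
    """
    rng = np.random.default_rng(seed)
    rows, cols = None, []
    sheet_rows = []
    values = []
    for (drug, t), mus in cell_means.items():
        for rep in range(n_rep):
            sid = f"{drug}_{t}_{rep}"
            sheet_rows.append({"sample_id": sid, "drug": drug, "time_h": t,
                               "batch": "b0", "arm": "vehicle",
                               "replicate": rep})
            col = np.asarray(mus, dtype=float)
            if noise is not None:
                col = col + rng.normal(0, noise, size=col.shape)
            values.append(col)
            cols.append(sid)
    mat = pd.DataFrame(np.column_stack(values),
                       index=[f"g{i}" for i in range(len(values[0]))],
                       columns=cols)
    return ExpressionData(values=mat, samples=pd.DataFrame(sheet_rows))


def anova_oracle(y: np.ndarray, drug: np.ndarray, time: np.ndarray):
    """Closed-form balanced two-way ANOVA for a single probe."""
    drugs, times = np.unique(drug), np.unique(time)
    a, b, N = len(drugs), len(times), y.size
    n = N // (a * b)
    g = y.mean()
    ssa = b * n * sum((y[drug == d].mean() - g) ** 2 for d in drugs)
    ssb = a * n * sum((y[time == t].mean() - g) ** 2 for t in times)
    ssc = n * sum((y[(drug == d) & (time == t)].mean() - g) ** 2
                  for d in drugs for t in times)
    sst = ((y - g) ** 2).sum()
    ssab, sse = ssc - ssa - ssb, sst - ssc
    dfe = N - a * b
    out = {}
    for name, ss, df in (("drug", ssa, a - 1), ("time", ssb, b - 1),
                         ("interaction", ssab, (a - 1) * (b - 1))):
        F = (ss / df) / (sse / dfe)
        out[name] = (F, stats.f.sf(F, df, dfe))
    return out


class TestTwoWayAnova:
    def test_matches_closed_form_oracle(self):
        cells = {("saline", 1): [0.0], ("saline", 2): [0.3],
                 ("drugX", 1): [1.2], ("drugX", 2): [0.1]}
        data = design_data(cells, noise=0.5, seed=3)
        res = fit_two_way_anova(data)
        sheet = data.samples
        y = data.values.iloc[0][sheet.sample_id].to_numpy()
        oracle = anova_oracle(y, sheet.drug.to_numpy(), sheet.time_h.to_numpy())
        row = res.table.iloc[0]
        for factor in ("drug", "time", "interaction"):
            assert row[f"F_{factor}"] == pytest.approx(oracle[factor][0])
            assert row[f"p_{factor}"] == pytest.approx(oracle[factor][1])

    def test_matches_statsmodels_cross_check(self):
        import statsmodels.api as smapi
        import statsmodels.formula.api as smf
        cells = {("saline", 1): [0.0], ("saline", 4): [0.5],
                 ("drugX", 1): [2.0], ("drugX", 4): [0.4]}
        data = design_data(cells, noise=0.7, seed=9)
        res = fit_two_way_anova(data)
        frame = data.samples.copy()
        frame["y"] = data.values.iloc[0][frame.sample_id].to_numpy()
        aov = smapi.stats.anova_lm(
            smf.ols("y ~ C(drug) * C(time_h)", data=frame).fit(), typ=2)
        assert res.table.iloc[0]["F_drug"] == pytest.approx(
            aov.loc["C(drug)", "F"])
        assert res.table.iloc[0]["p_interaction"] == pytest.approx(
            aov.loc["C(drug):C(time_h)", "PR(>F)"])

    def test_constant_probe_flagged_degenerate(self):
        cells = {("saline", 1): [1.0, 0.0], ("drugX", 1): [1.0, 2.0],
                 ("saline", 2): [1.0, 0.1], ("drugX", 2): [1.0, 1.5]}
        data = design_data(cells, noise=None)
        data.values.iloc[1] += np.random.default_rng(0).normal(
            0, 0.1, size=data.values.shape[1])
        res = fit_two_way_anova(data)
        row = res.table.iloc[0]
        assert row["degenerate"]
        assert row["F_drug"] == 0.0 and row["p_drug"] == 1.0
        assert not res.table.iloc[1]["degenerate"]

    def test_missing_cell_reported(self):
        cells = {("saline", 1): [0.0], ("saline", 2): [0.0],
                 ("drugX", 1): [1.0]}
        data = design_data(cells, noise=0.1)
        with pytest.raises(ValueError, match="empty design cells"):
            fit_two_way_anova(data)

    def test_naive_samples_excluded_from_model(self, small_sim):
        data, _ = small_sim
        res = fit_two_way_anova(data)
        # 7 drug levels (6 drugs + saline), not 8
        assert res.factors["drug"] == 6


class TestAdjustments:
    def test_bonferroni_arithmetic(self):
        np.testing.assert_allclose(adjust_bonferroni([0.0, 0.5], 3),
                                   [0.0, 1.0])
        assert bonferroni_threshold(0.05, 48000) == pytest.approx(1.0417e-6,
                                                                  rel=1e-3)

    def test_bonferroni_m_too_small_rejected(self):
        with pytest.raises(ValueError):
            adjust_bonferroni([0.1, 0.2], 1)

    def test_bh_step_up_hand_example(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(adjust_bh([0.2]), [0.2])

    def test_bh_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(5)
        p = rng.random(200)
        np.testing.assert_allclose(adjust_bh(p),
                                   multipletests(p, method="fdr_bh")[1],
                                   atol=1e-12)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
def test_adjustment_ordering_property(p):
    """Bonferroni >= BH >= raw p, and BH is monotone in the raw order."""
    p = np.asarray(p)
    bh = adjust_bh(p)
    bonf = adjust_bonferroni(p)
    assert (bonf >= bh - 1e-12).all()
    assert (bh >= p - 1e-12).all()
    order = np.argsort(p, kind="stable")
    assert (np.diff(bh[order]) >= -1e-12).all()


class TestTpCurve:
    def test_zero_fdr_level_counts_all_certain(self):
        q = np.array([0.0, 0.0, 0.5])
        c = tp_curve(q, grid=[0.0, 50.0])
        assert c.curve.TP.iloc[0] == 2

    def test_direct_formula(self):
        q = np.concatenate([np.full(100, 0.2), np.ones(400)])
        c = tp_curve(q, grid=[29.0])
        assert c.curve.N.iloc[0] == 100
        assert c.curve.TP.iloc[0] == 71

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            tp_curve(np.array([0.1]), grid=[])


class TestTukey:
    def test_two_group_critical_value_is_sqrt2_t(self):
        for df in (5, 20, 56):
            q2 = tukey_critical_value(0.05, 2, df)
            t = stats.t.ppf(1 - 0.025, df)
            assert q2 == pytest.approx(np.sqrt(2) * t, rel=1e-6)

    def test_critical_value_matches_published_table(self):
        # studentized-range table: q_{0.05}(k=3, df=10) = 3.88
        assert tukey_critical_value(0.05, 3, 10) == pytest.approx(3.88,
                                                                  abs=0.01)

    def test_identical_means_no_contrasts(self):
        cells = {("saline", 1): [0.0], ("drugX", 1): [0.0],
                 ("saline", 2): [0.0], ("drugX", 2): [0.0]}
        data = design_data(cells, noise=0.3, seed=2)
        res = fit_two_way_anova(data)
        tk = tukey_drug_vs_saline(res)
        assert not tk.significant.any()

    def test_hand_computed_q_statistic(self):
        cells = {("saline", 1): [0.0], ("drugX", 1): [3.0],
                 ("saline", 2): [0.0], ("drugX", 2): [0.0]}
        data = design_data(cells, noise=0.4, seed=8)
        res = fit_two_way_anova(data)
        tk = tukey_drug_vs_saline(res)
        row = tk[(tk.drug == "drugX") & (tk.time_h == 1)].iloc[0]
        diff = (res.cell_means[("drugX", 1)] - res.cell_means[("saline", 1)]
                ).iloc[0]
        se = np.sqrt(res.mse.iloc[0] / 3.0)   # equal n = 3 per cell
        assert row.q_stat == pytest.approx(abs(diff) / se)
        assert row.significant and row.direction == 1

    def test_planted_induction_detected(self, small_normalized, small_sim):
        _, truth = small_sim
        res = fit_two_way_anova(small_normalized)
        tk = tukey_drug_vs_saline(res)
        genes = truth.pattern_genes("A")
        hits = tk[(tk.probe.isin(genes)) & (tk.drug == "cocaine")
                  & (tk.time_h == 1)]
        assert (hits.significant & (hits.direction == 1)).mean() >= 0.9
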