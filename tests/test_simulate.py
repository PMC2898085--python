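import numpy as np
import pytest
from scipy import stats

import stridemod as sm
from stridemod.config import GroundTruth, SimulationConfig, null_config
from stridemod.simulate import (simulate_behavior, simulate_expression,
                                simulate_inhibitor_experiment,
                                simulate_promoters, synthetic_pwms,
                                truth_activation)


class TestExpression:
    def test_same_seed_identical_output(self):
        cfg = SimulationConfig(n_probes=200, seed=5)
        d1, t1 = simulate_expression(cfg)
        d2, t2 = simulate_expression(SimulationConfig(n_probes=200, seed=5))
        assert d1.values.equals(d2.values)
        assert t1.pattern_membership == t2.pattern_membership

    def test_null_model_constant_per_probe(self):
        cfg = null_config(n_probes=50, noise_sd=1e-9, batch_shift_sd=0.0,
                          diurnal_fraction=0.0, seed=0)
        data, _ = simulate_expression(cfg)
        spread = data.values.max(axis=1) - data.values.min(axis=1)
        assert (spread < 1e-6).all()

    def test_planted_effect_recovered_in_group_means(self):
        cfg = SimulationConfig(seed=2)
        data, truth = simulate_expression(cfg)
        sheet = data.samples
        coc = sheet[(sheet.drug == "cocaine") & (sheet.time_h == 1)].sample_id
        sal = sheet[(sheet.drug == "saline") & (sheet.time_h == 1)].sample_id
        genes = truth.pattern_genes("A")
        diffs = (data.values.loc[genes, list(coc)].mean(axis=1)
                 - data.values.loc[genes, list(sal)].mean(axis=1))
        expected = cfg.effect("A", "cocaine", 1)
        tol = 4 * cfg.noise_sd * np.sqrt(2.0 / cfg.replicates_per_group)
        assert (np.abs(diffs - expected) < tol).mean() > 0.99

    def test_diurnal_trend_spares_drug_contrast(self):
        cfg = null_config(n_probes=400, diurnal_fraction=1.0, seed=4)
        data, truth = simulate_expression(cfg)
        sheet = data.samples
        # diurnal probes vary over time but not between drug and saline
        t1 = sheet[sheet.time_h == 1].sample_id
        t4 = sheet[sheet.time_h == 4].sample_id
        probe = sorted(truth.diurnal_probes)[0]
        across_time = abs(data.values.loc[probe, list(t1)].mean()
                          - data.values.loc[probe, list(t4)].mean())
        coc = sheet[(sheet.drug == "cocaine") & (sheet.time_h == 1)].sample_id
        sal = sheet[(sheet.drug == "saline") & (sheet.time_h == 1)].sample_id
        drug_contrast = abs(data.values.loc[probe, list(coc)].mean()
                            - data.values.loc[probe, list(sal)].mean())
        assert drug_contrast < 1.0  # noise scale, no planted drug effect
        assert data.values.loc[probe].std() > 0

    def test_oversized_patterns_rejected(self):
        with pytest.raises(ValueError, match="pattern sizes"):
            SimulationConfig(n_probes=50)

    def test_unknown_drug_in_effect_profile_rejected(self):
        with pytest.raises(ValueError, match="unknown drugs"):
            SimulationConfig(effect_profile={"A": {"caffeine": {1: 1.0}}})


class TestPromoters:
    def test_zero_mutation_rate_gives_identical_pair(self):
        cfg = SimulationConfig(n_probes=300, pattern_sizes={"A": 3},
                               planted_motifs={"A": ("SYN_SRE", 0.0, 0.0)},
                               conserved_mutation_rate=0.0,
                               background_mutation_rate=0.0,
                               n_background_promoters=2, seed=1)
        _, truth = simulate_expression(cfg)
        prom = simulate_promoters(cfg, truth)
        for pair in prom.pairs.values():
            assert pair.target == pair.ortholog
            assert sm.conservation_mask(pair).all()

    def test_planting_rates_within_binomial_bounds(self):
        cfg = SimulationConfig(n_probes=600, pattern_sizes={"A": 40},
                               planted_motifs={"A": ("SYN_SRE", 0.6, 0.1)},
                               conserved_mutation_rate=0.0,
                               background_mutation_rate=0.0,
                               n_background_promoters=400, seed=7)
        _, truth = simulate_expression(cfg)
        prom = simulate_promoters(cfg, truth)
        consensus = synthetic_pwms()["SYN_SRE"].consensus
        fg = truth.pattern_genes("A")
        fg_hits = sum(consensus in prom.pairs[g].target for g in fg)
        bg = [g for g in prom.pairs if g not in fg]
        bg_hits = sum(consensus in prom.pairs[g].target for g in bg)
        lo_f, hi_f = stats.binom.ppf([0.005, 0.995], len(fg), 0.6)
        lo_b, hi_b = stats.binom.ppf([0.005, 0.995], len(bg), 0.1)
        assert lo_f <= fg_hits <= hi_f
        # chance occurrences can only add hits on top of planting
        assert lo_b <= bg_hits <= hi_b + 3

    def test_zero_planting_rate_leaves_only_chance_hits(self):
        cfg = SimulationConfig(n_probes=300, pattern_sizes={"A": 10},
                               planted_motifs={"A": ("SYN_SRE", 0.0, 0.0)},
                               n_background_promoters=40, seed=3)
        _, truth = simulate_expression(cfg)
        prom = simulate_promoters(cfg, truth)
        pwm = prom.pwms["SYN_SRE"]
        n_hit_genes = sum(
            bool(sm.scan_pwm(p.target, pwm)) for p in prom.pairs.values())
        # expected chance rate is well under 10% of genes for a 14-bp motif
        assert n_hit_genes <= 0.1 * len(prom.pairs)

    def test_motif_longer_than_window_rejected(self):
        cfg = SimulationConfig(n_probes=300, pattern_sizes={"A": 3},
                               conserved_window_bp=10,
                               planted_motifs={"A": ("SYN_SRE", 0.5, 0.1)},
                               n_background_promoters=2, seed=1)
        _, truth = simulate_expression(cfg)
        with pytest.raises(ValueError, match="longer than conserved window"):
            simulate_promoters(cfg, truth)


class TestBehavior:
    def test_noiseless_unit_slope_reproduces_activation(self):
        cfg = SimulationConfig(
            phenotype_link={"B1": ("cpp", 1.0, 0.0),
                            "A": ("locomotion", 1.0, 0.0)}, seed=0)
        truth = GroundTruth(phenotype_link=dict(cfg.phenotype_link))
        ph = simulate_behavior(truth, cfg)
        np.testing.assert_allclose(ph.cpp.to_numpy(),
                                   truth_activation(cfg, "B1", "summed"))
        np.testing.assert_allclose(
            ph.locomotion.to_numpy(),
            truth_activation(cfg, "A", "per_time").to_numpy())

    def test_zero_slope_breaks_link(self):
        cfg = SimulationConfig(
            phenotype_link={"B1": ("cpp", 0.0, 1.0)}, seed=0)
        truth = GroundTruth(phenotype_link=dict(cfg.phenotype_link))
        rs = []
        for seed in range(40):
            cfg.seed = seed
            ph = simulate_behavior(truth, cfg)
            act = truth_activation(cfg, "B1", "summed")
            rs.append(stats.pearsonr(act, ph.cpp[act.index])[0])
        assert abs(np.mean(rs)) < 0.3


class TestInhibitorExperiment:
    def _phi_estimate(self, phi, seed=0, noise=None):
        kw = {} if noise is None else {"noise_sd": noise}
        cfg = SimulationConfig(n_probes=200, pattern_sizes={"A": 30},
                               seed=seed, **kw)
        _, truth = simulate_expression(cfg)
        data = simulate_inhibitor_experiment(truth, {"A": phi}, cfg,
                                             drug="cocaine", time_h=1)
        res = sm.percent_inhibition(data, truth.pattern_genes("A"), "cocaine")
        return res

    def test_phi_zero_matches_drug_vehicle_arm(self):
        res = self._phi_estimate(0.0, noise=1e-9)
        assert res.percent_inhibition == pytest.approx(0.0, abs=1e-4)

    def test_phi_100_returns_to_baseline(self):
        res = self._phi_estimate(100.0, noise=1e-9)
        assert res.percent_inhibition == pytest.approx(100.0, abs=1e-4)

    def test_phi_126_drives_below_baseline(self):
        res = self._phi_estimate(126.0, noise=1e-9)
        assert res.percent_inhibition == pytest.approx(126.0, abs=1e-3)
        assert res.activation_inhibitor < 0

    def test_unknown_pattern_rejected(self):
        cfg = SimulationConfig(n_probes=200, pattern_sizes={"A": 5}, seed=0)
        _, truth = simulate_expression(cfg)
        with pytest.raises(ValueError, match="unknown pattern"):
            simulate_inhibitor_experiment(truth, {"Z": 10.0}, cfg)

    def test_planted_inhibition_recorded(self):
        cfg = SimulationConfig(n_probes=200, pattern_sizes={"A": 5}, seed=0)
        _, truth = simulate_expression(cfg)
        simulate_inhibitor_experiment(truth, {"A": 65.0}, cfg,
                                      drug="cocaine", time_h=1,
                                      experiment="exp1")
        assert truth.planted_inhibition[("exp1", "A")] == 65.0
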