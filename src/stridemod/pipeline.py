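"""End-to-end synthetic run: simulate -> preprocess -> discover ->
patterns -> enrich -> tfbs -> dissect -> network.

``run_pipeline`` generates a complete synthetic study, pushes it
through every analysis stage with default parameters, and writes each
declared text format into an output directory.  It returns a summary
dict with the in-memory results so the stages can be inspected
programmatically.  Discovered clusters (labeled C1, C2, ...) are
matched to the planted pattern labels by majority membership purely
for reporting; every statistic is computed from the data.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import dissect as dissect_mod
from . import network as network_mod
from . import patterns as patterns_mod
from . import preprocess, simulate
from .config import SimulationConfig
from .data import ExpressionData, write_expression_tsv
from .discover import fit_two_way_anova, tp_curve, tukey_drug_vs_saline
from .enrich import screen_collection
from .promoter_io import write_promoters
from .tfbs import (conservation_mask, conserved_hits, hits_to_bed,
                   promoter_presence, tfbs_enrichment, write_jaspar)

DEFAULT_FDR_GRID = [0.1, 1, 5, 10, 20, 29, 50, 70]


def _match_clusters_to_truth(core: dict[str, list[str]],
                             membership: dict[str, str]) -> dict[str, str]:
    """Majority-vote mapping of discovered cluster label -> planted label."""
    mapping = {}
    for label, genes in core.items():
        votes = pd.Series([membership.get(g, "none") for g in genes])
        mapping[label] = votes.mode().iloc[0]
    return mapping


def run_pipeline(outdir: str | Path, config: SimulationConfig | None = None,
                 seed: int | None = None) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = SimulationConfig()
    if seed is not None:
        config.seed = seed

    # -- simulate -------------------------------------------------------
    data, truth = simulate.simulate_expression(config)
    raw = ExpressionData(values=2.0 ** data.values, samples=data.samples,
                         log2=False)
    write_expression_tsv(raw, outdir / "expression_raw.tsv",
                         outdir / "samples.csv")
    truth.to_yaml(outdir / "truth.yaml")
    config.to_yaml(outdir / "sim_config.yaml")

    # -- preprocess -----------------------------------------------------
    normed = preprocess.standardize(
        preprocess.quantile_normalize(preprocess.log2_transform(raw)))
    write_expression_tsv(normed, outdir / "expression_normalized.tsv",
                         outdir / "samples.csv")

    # -- discover -------------------------------------------------------
    anova = fit_two_way_anova(normed)
    anova.table.to_csv(outdir / "anova.tsv", sep="\t", index_label="probe_id")
    curve = tp_curve(anova.table["q_bh_drug"].to_numpy(),
                     np.array(DEFAULT_FDR_GRID))
    curve.curve.to_csv(outdir / "tp_curve.tsv", sep="\t", index=False)
    tukey = tukey_drug_vs_saline(anova)
    tukey[tukey.significant].to_csv(outdir / "tukey_significant.tsv",
                                    sep="\t", index=False)
    significant = anova.table.index[
        anova.table["p_bonferroni_drug"] < 0.05].tolist()

    # -- patterns -------------------------------------------------------
    profiles = patterns_mod.build_profiles(normed)
    n_clusters = min(len(config.pattern_sizes), len(significant)) or None
    pattern_set = patterns_mod.cluster_genes(profiles.loc[significant],
                                             k=n_clusters, min_cluster_size=3)
    pattern_set = patterns_mod.extend_patterns(pattern_set, profiles)
    (outdir / "dendrogram.nwk").write_text(
        patterns_mod.to_newick(pattern_set) + "\n")
    rows = []
    for label, members in pattern_set.core.items():
        for g in members:
            rows.append({"gene": g, "pattern": label, "tier": "core",
                         "r": np.nan, "p": np.nan})
        for _, rec in pattern_set.extended[label].iterrows():
            rows.append({"gene": rec.gene, "pattern": label, "tier": "extended",
                         "r": rec.r, "p": rec.p})
    pd.DataFrame(rows).to_csv(outdir / "patterns.tsv", sep="\t", index=False)
    cluster_to_truth = _match_clusters_to_truth(pattern_set.core,
                                                truth.pattern_membership)

    # -- enrich ---------------------------------------------------------
    collection = simulate.simulate_gene_sets(config, truth)
    collection.to_gmt(outdir / "gene_sets.gmt")
    enrich_frames = []
    for label, members in pattern_set.core.items():
        hits = screen_collection(members, collection)
        hits.insert(0, "pattern", label)
        enrich_frames.append(hits)
    enrich_frames = [f for f in enrich_frames if not f.empty]
    enrichment = (pd.concat(enrich_frames, ignore_index=True) if enrich_frames
                  else pd.DataFrame())
    enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    # -- tfbs -----------------------------------------------------------
    promoters = simulate.simulate_promoters(config, truth)
    write_promoters(promoters, outdir / "promoters.fa")
    write_jaspar(promoters.pwms.values(), outdir / "pwms.jaspar")
    masks = {g: conservation_mask(p) for g, p in promoters.pairs.items()}
    all_hits = []
    tf_rows = []
    promoter_genes = list(promoters.pairs)
    for label, members in pattern_set.core.items():
        planted_pattern = cluster_to_truth.get(label, "none")
        pwm_id = dict(truth.planted_motifs).get(planted_pattern, (None,))[0]
        if pwm_id is None:
            continue
        pwm = promoters.pwms[pwm_id]
        fg = [g for g in members if g in promoters.pairs]
        if not fg:
            continue
        presence = promoter_presence(promoters.pairs, pwm, masks=masks)
        enr = tfbs_enrichment(fg, promoter_genes, presence, pwm_id=pwm_id)
        tf_rows.append({"pattern": label, "matrix_id": pwm_id,
                        "fold": enr.fold, "p": enr.p, "k": enr.k,
                        "n": enr.n, "K": enr.K, "N": enr.N})
        for g in fg:
            all_hits.extend(conserved_hits(promoters.pairs[g], pwm,
                                           mask=masks[g]))
    pd.DataFrame(tf_rows).to_csv(outdir / "tfbs_enrichment.tsv", sep="\t",
                                 index=False)
    hits_to_bed(all_hits, outdir / "tfbs_hits.bed")

    # -- dissect --------------------------------------------------------
    phi_plan = {"A": 126.0, "B1": 70.0}
    planted_phi = {lab: phi_plan[pat] for lab, pat in cluster_to_truth.items()
                   if pat in phi_plan}
    inhib = simulate.simulate_inhibitor_experiment(
        truth, {pat: phi_plan[pat] for pat in phi_plan}, config,
        drug="cocaine", time_h=1, experiment="cocaine_1h_antagonist")
    write_expression_tsv(inhib, outdir / "inhibitor_expression.tsv",
                         outdir / "inhibitor_samples.csv")
    dissection_results = []
    for label, target_phi in planted_phi.items():
        res = dissect_mod.percent_inhibition(
            inhib, pattern_set.core[label], drug="cocaine", pattern=label,
            experiment="cocaine_1h_antagonist")
        dissection_results.append(res)
    dissect_mod.dissection_table(dissection_results).to_csv(
        outdir / "dissection.tsv", sep="\t", index=False)

    # -- integrate ------------------------------------------------------
    phenotypes = simulate.simulate_behavior(truth, config)
    phenotypes.to_csv(outdir / "phenotypes.csv")
    corr_rows = []
    for label, members in pattern_set.core.items():
        summed = network_mod.pattern_activation(profiles, members, "summed")
        drugs = [d for d in summed.index if d in phenotypes.cpp.index]
        r, p = network_mod.correlate(summed[drugs], phenotypes.cpp[drugs])
        corr_rows.append({"pattern": label, "phenotype": "cpp",
                          "r": r, "p": p})
        per_time = network_mod.pattern_activation(profiles, members, "per_time")
        loco = phenotypes.locomotion.loc[per_time.index, per_time.columns]
        r, p = network_mod.correlate(per_time.to_numpy().ravel(),
                                     loco.to_numpy().ravel())
        corr_rows.append({"pattern": label, "phenotype": "locomotion",
                          "r": r, "p": p})
    correlations = pd.DataFrame(corr_rows)
    correlations.to_csv(outdir / "phenotype_correlations.tsv", sep="\t",
                        index=False)

    membership = {g: lab for lab, genes in pattern_set.core.items()
                  for g in genes}
    net = network_mod.build_network(profiles.loc[significant], membership,
                                    tfbs_hits=all_hits,
                                    dissection_results=dissection_results)
    network_mod.export_network(net, outdir / "network.graphml", "graphml")
    network_mod.export_network(net, outdir / "network.sif", "sif")

    return {
        "config": config, "truth": truth, "normalized": normed,
        "anova": anova, "tp_curve": curve, "pattern_set": pattern_set,
        "cluster_to_truth": cluster_to_truth,
        "dissection": dissection_results, "correlations": correlations,
        "network": net, "outdir": outdir,
    }
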