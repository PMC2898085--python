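"""Conserved-promoter TFBS scanning and per-pattern over-representation.

Simulates aligned mouse/ortholog promoter pairs with a motif planted in
conserved windows of pattern-A promoters, masks conserved positions
(70% identity in 50-bp alignment windows), scans with the motif's PWM
and tests presence enrichment in the pattern against the background.
"""

import stridemod as sm
from stridemod.config import SimulationConfig
from stridemod.tfbs import (conservation_mask, conserved_hits,
                            promoter_presence, tfbs_enrichment)

cfg = SimulationConfig(n_probes=600, pattern_sizes={"A": 40},
                       planted_motifs={"A": ("SYN_SRE", 0.6, 0.1)},
                       n_background_promoters=400, seed=4)
_, truth = sm.simulate_expression(cfg)
promoters = sm.simulate_promoters(cfg, truth)
pwm = promoters.pwms["SYN_SRE"]

example_gene = truth.pattern_genes("A")[0]
pair = promoters.pairs[example_gene]
mask = conservation_mask(pair)
hits = conserved_hits(pair, pwm, mask=mask)
print(f"{example_gene}: {mask.mean():.1%} of the promoter is conserved; "
      f"{len(hits)} conserved {pwm.matrix_id} site(s)")
for h in hits[:3]:
    print(f"   site at {h.start:+d} bp from TSS, strand {h.strand}, "
          f"relative score {h.rel_score:.2f}")

presence = promoter_presence(promoters.pairs, pwm)
enr = tfbs_enrichment(truth.pattern_genes("A"), list(promoters.pairs),
                      presence, pwm_id=pwm.matrix_id)
print(f"enrichment: fold = {enr.fold:.1f} (p = {enr.p:.2g}); "
      f"{enr.k}/{enr.n} pattern promoters vs {enr.K}/{enr.N} overall")
print("-> fold > 3 with small p recovers the planted foreground/background"
      " planting rates (0.6 vs 0.1)")
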