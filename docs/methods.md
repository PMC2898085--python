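# Methods

This note documents the models, numerical choices and known
limitations behind `stridemod`, in the package's own terms.

## Study design being modeled

The analysis chain targets a single-dose drug x time-course expression
experiment: six drugs of abuse (cocaine, methamphetamine, morphine,
heroin, ethanol, nicotine) plus saline-injected and naive controls,
profiled at 1, 2, 4 and 8 h after injection with three replicate
arrays per group, hybridized in two batches.  Saline is treated as a
seventh drug level in the ANOVA; naive arrays are excluded from the
model and exist to separate injection stress and diurnal drift from
drug effects.

## Synthetic-data generator

`simulate_expression` builds a log2-scale matrix as

    baseline_p + effect(pattern(p), drug(s), time(s))
               + diurnal_p(time(s)) + batch_shift(p, batch(s)) + noise

* **Baseline** per probe ~ N(7, 1) log2 units, the typical scale of
  array intensities after background correction.
* **Pattern effects.**  Probes are assigned disjointly to patterns A
  (38 probes), B1 (45), B2 (31), B3 (18); the effect table (editable
  YAML via `SimulationConfig`) encodes the temporal logic: A rises at
  1–2 h under psychostimulants and at 4 h under opioids, never under
  ethanol/nicotine; B1 rises at 1–2 h under every drug to a different
  degree; B2 at 2–4 h under ethanol/opioids/methamphetamine; B3 at
  4–8 h under ethanol/opioids.  Effects are capped at 1.5 log2 units —
  clear but unsaturated separation at the default noise.
* **Diurnal background.**  30% of background probes get a sinusoid
  with a 24 h period, amplitude ~ U(0.3, 1.5) and random phase,
  applied identically to every arm.  This reproduces the qualitative
  situation where the time factor alters far more of the transcriptome
  than the drug factor without ever loading on the drug factor.
* **Batch and noise.**  Batch shifts are additive per (probe, batch),
  sd 0.1; residual noise is i.i.d. Gaussian, sd 0.2 log2 units,
  interpreted as post-pooling array variability (animals and pooling
  are not modeled — the pipeline never sees animal identity).
* **Determinism.**  All randomness flows from `default_rng([seed,
  stream, substream])` with fixed stream tags per generator, so one
  (config, seed) pair reproduces every output byte-for-byte.

`simulate_promoters` emits gap-free target/ortholog alignments of
6001 bp (−5000..+1000 around the TSS): eight 120-bp conserved windows
mutated at rate 0.05, the remainder at 0.5.  The 0.5 background rate
keeps non-conserved sequence safely below the 70% identity bar — at
0.6 identity, a 50-bp window clears 70% with ~7% probability, which
floods the conservation mask with spurious patches.  Motif instances
are exact consensus copies planted inside conserved windows at rate
0.6 for the pattern's own genes and 0.1 elsewhere.  The built-in
matrix library is synthetic: four sharp 14–15 bp consensus matrices
(85:5:5:5 column counts) loosely shaped after serum-response,
forkhead, nuclear-receptor and glucocorticoid elements.  The lengths
were chosen so that a chance hit at relative score ≥ 0.8 within a
promoter's conserved sequence stays below ~1% per gene; shorter
(8–10 bp) motifs give per-gene chance-hit rates of tens of percent and
dilute the planted fold enrichments.

`simulate_inhibitor_experiment` plants a linear-scale attenuation: if
a pattern gene's drug activation is a = 2^effect − 1, the
drug+inhibitor arm gets log2(1 + (1 − φ/100)·a), so φ > 100 puts the
arm below the saline baseline and φ < 0 amplifies.
`simulate_behavior` links place preference to the summed early-wave
(B1) activation and locomotion to the per-time immediate-early (A)
activation, slope 1 and additive noise sd 0.1 in activation units —
with only six drugs contributing points to the CPP correlation, much
larger noise makes the n = 6 Pearson correlation uninformative for any
method.

What the generator does **not** emulate: bead-level array artifacts,
probe cross-annotation between array versions, animal-level pooling
variance, indels in promoter alignments, soft (degenerate) motif
instances, and any dependence structure between probes beyond the
planted patterns.  Passing recovery tests therefore demonstrate that
the chain is correct and calibrated under its stated noise model, not
that it is robust to every failure mode of real arrays.

## Normalization and calibration

Quantile normalization maps each column onto the row-mean reference
distribution; ties within a column receive the mean of the reference
values over the tied rank span, the common dialect.  Background
subtraction is assumed done upstream.

Standardization is per probe within hybridization batch (z-score),
which removes additive and multiplicative batch distortions while
preserving within-batch group contrasts.  Centering each probe within
B batches consumes B − 1 residual degrees of freedom that the
downstream F-test would otherwise attribute to noise; the transform
records this on the data (`df_adjustment`) and `fit_two_way_anova`
subtracts it from the residual df.  Without the correction the drug
factor's null p-values are detectably anticonservative (a ~2% F
inflation is visible to a Kolmogorov–Smirnov test at 5000 probes);
with it, null p-values are uniform.  The alternative `per_array`
z-scoring mode is provided but not default.

## Discovery

Balanced designs use classical two-way sums of squares, vectorized
across probes; unbalanced designs fall back to per-probe Type II
fits via statsmodels.  Probes with zero total variance are flagged
degenerate and reported as F = 0, p = 1 so downstream counts stay
stable.  Bonferroni uses m = number of probes actually tested.  The
interaction term is included by default.

The true-positive curve reports TP(q) = N(q)·(1 − q/100) on a percent
grid (default 0.1–70).  TP at very loose q is high-variance: the BH
rejection boundary crosses the p-value order statistics at a shallow
angle, so the crossing point (and hence N(q)) fluctuates strongly even
for perfectly calibrated p-values.  The curve therefore reports, next
to the max and its argmax, a robust `plateau_tp` — the median TP over
the grid — as the plateau-height estimate; recovery tests target the
plateau, not the max.

Tukey contrasts treat all drug x time cell means as one family
(28 cells in the default design) and surface only each drug against
time-matched saline, with the Tukey–Kramer standard error and the
studentized-range critical value.  By default only the
significant/direction calls are computed; per-contrast p-values are
optional because `studentized_range.sf` is much slower than one `ppf`
call.

## Patterns

Profiles for clustering are standardized saline-referenced group means
(drug-cell mean minus time-matched saline mean; 6 drugs x 4 times =
24 columns) — group-mean profiles cluster more stably than per-array
values.  Average-linkage agglomeration on Euclidean distances; genes
are sorted lexicographically before linkage so the result is
order-independent.  The default cut height h = 13 is scale-dependent
and kept only as a nominal default; the `k`-cut is the recommended
mode, and with `min_cluster_size > 1` the cut deepens until k
substantive clusters exist, so a single outlier profile cannot absorb
a cluster slot (outliers remain visible as extra small clusters).  An
optional 3-SD distance-to-centroid outlier filter is available but
off by default.

Extension correlates every gene's profile against the core-cluster
centroid (columnwise mean) and admits genes at two-sided p < 1e-10
from the t-transform of r on n − 2 df.  At n = 24 columns this
corresponds to |r| ≳ 0.916, which keeps the transcriptome-wide false
inclusion rate effectively at zero.  Overlap between extended lists is
reported relative to the smaller list, with the denominator convention
recorded in the output rather than assumed.

## Enrichment and TFBS analysis

Over-representation is a flat per-term screen: hypergeometric upper
tail (one-sided Fisher), fold = (k/n)/(K/N), BH across the whole
collection per query, and a report filter of k ≥ 3 and p < 0.05.
The background universe defaults to all probes.  Cell-type labels use
inclusive fold tiers (2, 5, 20).

PWM scores are additive log2 odds with pseudocount mass 0.8 per
column distributed by the background frequencies; N scores zero.
Hits are reported at relative score ≥ 0.8 (the conventional scanning
default), both strands, 0-based half-open TSS-relative coordinates.
Conservation masking slides a 50-bp window over alignment columns
(identity threshold 0.70, gaps count as mismatches) and a position is
conserved if any covering window qualifies; the per-promoter,
per-matrix cap of 50 conserved hits keeps the top-scoring sites
(ties by position, then strand).  The cap is interpreted per
promoter-and-matrix; other readings (per promoter across matrices, a
ranking filter) exist and the choice is surfaced in configuration.

## Dissection

Fold changes are linear scale (2^Δlog2 of arm means over
saline+vehicle of the same experiment), activation is mean FC − 1, and
φ = (1 − a_i/a_d)·100.  Results are flagged unreliable when |a_d| is
below 0.1 — percent inhibition of a near-zero response is not
meaningful.  The pairing unit of the significance test is the gene
(paired t across pattern genes of the two FC vectors); identical
vectors return p = 1 with a degenerate flag.  Whether to average fold
changes or fold-change the averages is switchable; mean-of-FC is the
default.

## Integration

Pattern activation is the mean saline-referenced profile over pattern
genes, summarized per drug x time (`per_time`) or summed over time
points per drug (`summed`); the summed mode feeds the CPP correlation
(n = 6 drugs), the per-time mode the locomotion correlation (n = 24).
Correlations are Pearson by default, Spearman available (used e.g. for
array/qPCR agreement).  The network is a typed directed graph:
co-expression edges require r strictly greater than 0.6, TF→gene edges
require a conserved binding site, signaling→pattern edges require
dissection p < 0.1.  GraphML round-trips all attributes; SIF is
intentionally lossy.

## Problem sizes in tests

The test suite checks calibration on 100 global-null simulations of
5000 probes (uniformity is asserted on the first 20), parameter
recovery on batches of 10–50 seeds at default conditions, TFBS
recovery on 20 simulations of 440 promoters, and inhibition recovery
on 50 seeds per planted φ in {0, 30, 65, 100, 126}.  The TP-plateau
recovery check plants 100 drug-responsive probes (pattern sizes
29/34/23/14) so the plateau target is a round planted count; the
package default remains 38/45/31/18.

## Known limitations

* The unbalanced-design ANOVA path loops per probe and is orders of
  magnitude slower than the balanced path.
* h-based dendrogram cuts are scale-dependent; use the k-cut unless
  profile units are fixed.
* The TFBS stage assumes pre-aligned promoter pairs and does not
  compute alignments.
* Quantile normalization with a large fraction of strongly regulated
  probes (≫5%) leaks signal into null probes; at the simulated 2–3%
  responsive fraction the effect is negligible but it is not corrected
  for.
* Tukey p-values (as opposed to significance calls) are expensive at
  transcriptome scale.
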