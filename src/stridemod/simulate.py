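"""Synthetic-data generator with a planted-truth ledger.

Generates every input the pipeline consumes: a drug x time expression
matrix with co-expression patterns, diurnal background trends, batch
shifts and Gaussian noise; aligned promoter pairs with motifs planted
in conserved windows; behavioral tables linked to pattern activation;
and four-arm inhibitor experiments with a known percent inhibition.
Identical (config, seed) reproduces every output exactly.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import GroundTruth, SimulationConfig
from .data import NAIVE, SALINE, ExpressionData, PhenotypeTable
from .tfbs import PWM, PromoterPair, PromoterSet

# fixed RNG substream tags so each generator is independent of the others
_STREAM_EXPRESSION = 1
_STREAM_PROMOTERS = 2
_STREAM_BEHAVIOR = 3
_STREAM_INHIBITOR = 4

#: Consensus strings of the synthetic motif library (one per pattern).
#: Shapes are loosely modeled on serum-response, forkhead, nuclear-receptor
#: and glucocorticoid-response elements but are synthetic constructions.
SYNTHETIC_MOTIF_CONSENSUS = {
    "SYN_SRE": "GTCCATATTAGGCA",
    "SYN_FRE": "CATGTTTACTTTGA",
    "SYN_NRE": "CAGGTCAAGGTCAG",
    "SYN_GRE": "AGAACATTATGTTCT",
}


def synthetic_pwms() -> dict[str, PWM]:
    """The built-in PWM library used by the promoter simulator."""
    return {mid: PWM.from_consensus(mid, cons)
            for mid, cons in SYNTHETIC_MOTIF_CONSENSUS.items()}


def _rng(config: SimulationConfig, stream: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream, extra])


def _probe_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"probe_{i:0{width}d}" for i in range(n)]


def _assign_truth(config: SimulationConfig,
                  rng: np.random.Generator) -> GroundTruth:
    probes = _probe_ids(config.n_probes)
    membership: dict[str, str] = {}
    i = 0
    for pattern, size in config.pattern_sizes.items():
        for _ in range(size):
            membership[probes[i]] = pattern
            i += 1
    background = probes[i:]
    n_diurnal = int(round(config.diurnal_fraction * config.n_probes))
    diurnal = set(rng.choice(background, size=min(n_diurnal, len(background)),
                             replace=False).tolist())
    return GroundTruth(
        pattern_membership=membership,
        diurnal_probes=diurnal,
        planted_motifs=dict(config.planted_motifs),
        phenotype_link=dict(config.phenotype_link),
    )


def _sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    """Main-experiment design: drugs + saline + naive, all time points."""
    rows = []
    for drug in config.drugs + [SALINE, NAIVE]:
        arm = "naive" if drug == NAIVE else "vehicle"
        for t in config.time_points:
            for rep in range(config.replicates_per_group):
                rows.append({
                    "sample_id": f"{drug}_{t}h_r{rep}",
                    "drug": drug, "time_h": t,
                    "batch": f"batch{rep % config.batches}",
                    "arm": arm, "replicate": rep,
                })
    return pd.DataFrame(rows)


def simulate_expression(config: SimulationConfig,
                        ) -> tuple[ExpressionData, GroundTruth]:
    """Generate the primary drug x time-course expression matrix (log2).

    Per probe and sample: baseline + planted pattern effect (from
    ``config.effect_profile``, applied to drug arms only) + a sinusoidal
    24 h diurnal trend on diurnal probes (identical across drug, saline
    and naive arms) + per-(probe, batch) shift + Gaussian noise.
    """
    truth = _assign_truth(config, _rng(config, _STREAM_EXPRESSION, 0))
    rng = _rng(config, _STREAM_EXPRESSION, 1)
    sheet = _sample_sheet(config)
    probes = _probe_ids(config.n_probes)
    P, S = len(probes), len(sheet)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=P)
    mat = np.tile(baseline[:, None], (1, S))

    # planted pattern effects
    probe_index = {p: i for i, p in enumerate(probes)}
    time_arr = sheet["time_h"].to_numpy()
    drug_arr = sheet["drug"].to_numpy()
    for probe, pattern in truth.pattern_membership.items():
        i = probe_index[probe]
        for drug, per_time in config.effect_profile.get(pattern, {}).items():
            for t, eff in per_time.items():
                mat[i, (drug_arr == drug) & (time_arr == t)] += eff

    # diurnal background: amplitude and phase per probe, 24 h period
    diurnal_idx = np.array(sorted(probe_index[p] for p in truth.diurnal_probes),
                           dtype=int)
    if diurnal_idx.size:
        lo, hi = config.diurnal_amplitude
        amp = rng.uniform(lo, hi, size=diurnal_idx.size)
        phase = rng.uniform(0, 2 * math.pi, size=diurnal_idx.size)
        phase_t = 2 * math.pi * time_arr / 24.0
        mat[diurnal_idx, :] += amp[:, None] * np.sin(phase_t[None, :]
                                                     + phase[:, None])

    # per-(probe, batch) hybridization shift
    batches = sorted(sheet["batch"].unique())
    shifts = rng.normal(0.0, config.batch_shift_sd, size=(P, len(batches)))
    for bi, batch in enumerate(batches):
        mat[:, (sheet["batch"] == batch).to_numpy()] += shifts[:, [bi]]

    mat += rng.normal(0.0, config.noise_sd, size=(P, S))

    values = pd.DataFrame(mat, index=probes, columns=sheet["sample_id"].tolist())
    return ExpressionData(values=values, samples=sheet, log2=True), truth


# ---------------------------------------------------------------------------
# promoters


def simulate_promoters(config: SimulationConfig, truth: GroundTruth,
                       ) -> PromoterSet:
    """Aligned promoter pairs with motifs planted in conserved windows.

    Every pattern gene receives a promoter; ``n_background_promoters``
    additional background genes are drawn from the non-pattern probes.
    The ortholog is a copy of the target mutated at
    ``background_mutation_rate`` outside designated conserved windows
    and at ``conserved_mutation_rate`` inside them (no indels, so the
    alignment is gap-free).  For each pattern's motif, an exact
    consensus instance is planted in a random conserved window at the
    foreground rate for that pattern's genes and at the background rate
    for all other promoters.
    """
    if not truth.planted_motifs:
        raise ValueError("truth has no planted_motifs")
    rng = _rng(config, _STREAM_PROMOTERS)
    pwms = synthetic_pwms()
    for pattern, (pwm_id, _, _) in truth.planted_motifs.items():
        if pwm_id not in pwms:
            raise ValueError(f"unknown PWM id {pwm_id!r} for pattern {pattern}")
        if pwms[pwm_id].length > config.conserved_window_bp:
            raise ValueError("motif longer than conserved window")

    pattern_genes = sorted(truth.pattern_membership)
    background_pool = [p for p in _probe_ids(config.n_probes)
                       if p not in truth.pattern_membership]
    n_bg = min(config.n_background_promoters, len(background_pool))
    bg_genes = sorted(rng.choice(background_pool, size=n_bg, replace=False))
    genes = pattern_genes + list(bg_genes)

    L = config.promoter_length
    W = config.conserved_window_bp
    n_win = config.n_conserved_windows
    base_arr = np.frombuffer(b"ACGT", dtype="S1").astype("U1")

    pairs: dict[str, PromoterPair] = {}
    for gene in genes:
        target = rng.integers(0, 4, size=L)
        # non-overlapping conserved windows on a fixed lattice of slots
        slots = np.arange(0, L - W + 1, W)
        starts = rng.choice(slots, size=min(n_win, len(slots)), replace=False)
        conserved = np.zeros(L, dtype=bool)
        for s in starts:
            conserved[s: s + W] = True
        rate = np.where(conserved, config.conserved_mutation_rate,
                        config.background_mutation_rate)
        mutate = rng.random(L) < rate
        # substitute with one of the three other bases
        ortho = target.copy()
        ortho[mutate] = (target[mutate] + rng.integers(1, 4, size=mutate.sum())) % 4

        # motif planting: identical instance in both sequences, inside a
        # conserved window, so the site survives conservation masking
        gene_pattern = truth.pattern_membership.get(gene)
        for pattern, (pwm_id, fg_rate, bg_rate) in sorted(truth.planted_motifs.items()):
            rate_g = fg_rate if gene_pattern == pattern else bg_rate
            if rng.random() >= rate_g:
                continue
            pwm = pwms[pwm_id]
            win = starts[rng.integers(len(starts))]
            off = int(win + rng.integers(0, W - pwm.length + 1))
            inst = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b]
                             for b in pwm.consensus])
            target[off: off + pwm.length] = inst
            ortho[off: off + pwm.length] = inst

        pairs[gene] = PromoterPair(
            gene=gene,
            target="".join(base_arr[target]),
            ortholog="".join(base_arr[ortho]),
            tss=config.tss_offset,
        )
    return PromoterSet(pairs=pairs, pwms=pwms)


# ---------------------------------------------------------------------------
# gene-set collections


def simulate_gene_sets(config: SimulationConfig, truth: GroundTruth,
                       n_random_sets: int = 40,
                       random_set_size: tuple[int, int] = (10, 60),
                       signal_recall: float = 0.8,
                       ) -> "GeneSetCollection":
    """A literature-style gene-set collection with planted signal sets.

    For each planted pattern, one set contains ``signal_recall`` of the
    pattern's genes plus random background genes (emulating an earlier
    study that reported an overlapping list); ``n_random_sets``
    additional sets are drawn uniformly from the universe.
    """
    from .enrich import GeneSetCollection

    rng = _rng(config, _STREAM_EXPRESSION, 99)
    universe = _probe_ids(config.n_probes)
    sets: dict[str, set[str]] = {}
    for pattern in sorted(config.pattern_sizes):
        members = truth.pattern_genes(pattern)
        n_keep = int(round(signal_recall * len(members)))
        keep = rng.choice(members, size=n_keep, replace=False).tolist()
        pad = rng.choice(universe, size=max(5, len(members) // 2),
                         replace=False).tolist()
        sets[f"planted_{pattern}_study"] = set(keep) | set(pad)
    lo, hi = random_set_size
    for i in range(n_random_sets):
        size = int(rng.integers(lo, hi + 1))
        sets[f"random_set_{i:03d}"] = set(
            rng.choice(universe, size=size, replace=False).tolist())
    return GeneSetCollection(name="synthetic_literature", sets=sets,
                             universe=set(universe))


# ---------------------------------------------------------------------------
# behavior


def truth_activation(config: SimulationConfig, pattern: str,
                     mode: str = "summed") -> pd.Series | pd.DataFrame:
    """Planted activation of a pattern from the effect-profile table.

    ``summed``: per drug, the sum of log2 effects over time points.
    ``per_time``: per drug x time log2 effect matrix.
    """
    table = pd.DataFrame(
        [[config.effect(pattern, d, t) for t in config.time_points]
         for d in config.drugs],
        index=config.drugs, columns=config.time_points)
    if mode == "per_time":
        return table
    if mode == "summed":
        return table.sum(axis=1)
    raise ValueError(f"unknown mode {mode!r}")


def simulate_behavior(truth: GroundTruth, config: SimulationConfig,
                      ) -> PhenotypeTable:
    """Behavioral tables linked to planted pattern activation.

    CPP score per drug = slope * (summed activation of the CPP-linked
    pattern) + noise; locomotion per drug x time = slope * (per-time
    activation of the locomotion-linked pattern) + noise.
    """
    rng = _rng(config, _STREAM_BEHAVIOR)
    cpp = pd.Series(0.0, index=config.drugs)
    loco = pd.DataFrame(0.0, index=config.drugs, columns=config.time_points)
    for pattern, (phenotype, slope, noise_sd) in truth.phenotype_link.items():
        if phenotype == "cpp":
            act = truth_activation(config, pattern, "summed")
            cpp = slope * act + rng.normal(0, noise_sd, size=len(act))
        elif phenotype == "locomotion":
            act = truth_activation(config, pattern, "per_time")
            loco = slope * act + rng.normal(0, noise_sd, size=act.shape)
        else:
            raise ValueError(f"unknown phenotype {phenotype!r}")
    return PhenotypeTable(cpp=cpp, locomotion=loco)


# ---------------------------------------------------------------------------
# inhibitor experiments


def simulate_inhibitor_experiment(truth: GroundTruth, phi: dict[str, float],
                                  config: SimulationConfig,
                                  drug: str = "cocaine", time_h: int = 1,
                                  experiment: str | None = None,
                                  ) -> ExpressionData:
    """Four-arm dissection experiment with planted percent inhibition.

    Arms: saline+vehicle, drug+vehicle, saline+inhibitor, drug+inhibitor,
    each with ``replicates_per_group`` arrays at a single time point.
    For a pattern gene with drug-induced linear activation
    a = 2**effect - 1, the drug+inhibitor arm is planted at activation
    (1 - phi/100) * a; phi may be < 0 (amplification) or > 100
    (suppression below the saline baseline).  The planted values are
    recorded in ``truth.planted_inhibition``.
    """
    for pattern in phi:
        if pattern not in config.pattern_sizes:
            raise ValueError(f"unknown pattern key {pattern!r}")
        if not np.isfinite(phi[pattern]):
            raise ValueError("phi must be finite")
    if drug not in config.drugs:
        raise ValueError(f"unknown drug {drug!r}")
    experiment = experiment or f"{drug}_{time_h}h_inhibitor"
    rng = _rng(config, _STREAM_INHIBITOR,
               abs(hash(experiment)) % (2 ** 31))

    arms = [(SALINE, "vehicle"), (drug, "vehicle"),
            (SALINE, "inhibitor"), (drug, "inhibitor")]
    rows = []
    for arm_drug, arm in arms:
        for rep in range(config.replicates_per_group):
            rows.append({
                "sample_id": f"{arm_drug}_{arm}_r{rep}",
                "drug": arm_drug, "time_h": time_h, "batch": "batch0",
                "arm": arm, "replicate": rep,
            })
    sheet = pd.DataFrame(rows)

    probes = _probe_ids(config.n_probes)
    probe_index = {p: i for i, p in enumerate(probes)}
    P, S = len(probes), len(sheet)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=P)
    mat = np.tile(baseline[:, None], (1, S))

    is_drug_veh = ((sheet.drug == drug) & (sheet.arm == "vehicle")).to_numpy()
    is_drug_inh = ((sheet.drug == drug) & (sheet.arm == "inhibitor")).to_numpy()
    for probe, pattern in truth.pattern_membership.items():
        eff = config.effect(pattern, drug, time_h)
        if eff == 0.0:
            continue
        i = probe_index[probe]
        mat[i, is_drug_veh] += eff
        frac = 1.0 - phi.get(pattern, 0.0) / 100.0
        residual = 1.0 + frac * (2.0 ** eff - 1.0)  # linear-scale activation
        if residual <= 0:
            raise ValueError("phi drives expression to a nonpositive level")
        mat[i, is_drug_inh] += math.log2(residual)

    mat += rng.normal(0.0, config.noise_sd, size=(P, S))
    for pattern, value in phi.items():
        truth.planted_inhibition[(experiment, pattern)] = float(value)

    values = pd.DataFrame(mat, index=probes, columns=sheet["sample_id"].tolist())
    return ExpressionData(values=values, samples=sheet, log2=True)
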