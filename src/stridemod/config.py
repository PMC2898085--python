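"""Simulation configuration and ground-truth ledger.

The synthetic study reproduces the design of a drug x time-course
microarray experiment in mouse striatum: six drugs of abuse plus saline
and naive controls, four post-injection time points (1, 2, 4, 8 h),
three array replicates per group, and two hybridization batches.
Roughly one hundred probes are organized into four co-expression
patterns (A, B1, B2, B3) with drug- and time-specific induction; a
large fraction of background probes carry diurnal (time-factor) trends.

Effect sizes are log2-scale group-mean shifts relative to time-matched
saline, capped at 1.5 to give clear but unsaturated separation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Drugs of the primary experiment, in canonical order.
DEFAULT_DRUGS = [
    "cocaine", "methamphetamine", "morphine", "heroin", "ethanol", "nicotine",
]

DEFAULT_TIME_POINTS = [1, 2, 4, 8]

DEFAULT_PATTERN_SIZES = {"A": 38, "B1": 45, "B2": 31, "B3": 18}

#: log2 effect of each (pattern, drug, time) combination.
#: Pattern A: immediate-early response -- fast for psychostimulants,
#: delayed (4 h) for opioids, absent for ethanol and nicotine.
#: B1: early wave induced by every drug to a different degree.
#: B2: intermediate wave (2-4 h) for ethanol/opioids/methamphetamine.
#: B3: late wave (4-8 h) for ethanol and opioids.
DEFAULT_EFFECT_PROFILE: dict[str, dict[str, dict[int, float]]] = {
    "A": {
        "cocaine": {1: 1.5, 2: 1.5, 4: 0.5},
        "methamphetamine": {1: 1.5, 2: 1.4, 4: 0.5},
        "morphine": {4: 1.2, 8: 0.4},
        "heroin": {4: 1.2, 8: 0.4},
    },
    "B1": {
        "cocaine": {1: 1.0, 2: 1.0},
        "methamphetamine": {1: 0.9, 2: 0.9},
        "morphine": {1: 1.2, 2: 1.4},
        "heroin": {1: 1.2, 2: 1.4},
        "ethanol": {1: 0.8, 2: 0.8},
        "nicotine": {1: 0.3, 2: 0.4},
    },
    "B2": {
        "ethanol": {2: 0.8, 4: 1.4},
        "morphine": {2: 0.8, 4: 1.4},
        "heroin": {2: 0.8, 4: 1.4},
        "methamphetamine": {2: 0.4, 4: 0.7},
    },
    "B3": {
        "ethanol": {2: 0.5, 4: 1.5, 8: 1.0},
        "morphine": {2: 0.5, 4: 1.5, 8: 1.0},
        "heroin": {2: 0.5, 4: 1.5, 8: 1.0},
    },
}

#: Motif planting per pattern: (pwm id, foreground rate, background rate).
DEFAULT_PLANTED_MOTIFS = {
    "A": ("SYN_SRE", 0.6, 0.1),
    "B1": ("SYN_FRE", 0.6, 0.1),
    "B2": ("SYN_NRE", 0.6, 0.1),
    "B3": ("SYN_GRE", 0.6, 0.1),
}

#: Pattern -> (phenotype name, slope, additive noise sd).  CPP tracks the
#: summed early-wave (B1) activation; locomotion tracks the per-time
#: immediate-early (A) activation.
DEFAULT_PHENOTYPE_LINK = {
    "B1": ("cpp", 1.0, 0.1),
    "A": ("locomotion", 1.0, 0.1),
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults emulate the design described in the module docstring;
    ``effect_profile`` maps pattern -> drug -> {time_h: log2 effect}.
    """

    n_probes: int = 5000
    drugs: list[str] = field(default_factory=lambda: list(DEFAULT_DRUGS))
    time_points: list[int] = field(default_factory=lambda: list(DEFAULT_TIME_POINTS))
    replicates_per_group: int = 3
    batches: int = 2
    pattern_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PATTERN_SIZES))
    effect_profile: dict[str, dict[str, dict[int, float]]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_EFFECT_PROFILE))
    diurnal_fraction: float = 0.3
    diurnal_amplitude: tuple[float, float] = (0.3, 1.5)
    noise_sd: float = 0.2
    batch_shift_sd: float = 0.1
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    # promoter simulation
    promoter_length: int = 6001       # -5000..+1000 around the TSS
    tss_offset: int = 5000            # index of the TSS in the sequence
    n_conserved_windows: int = 8
    conserved_window_bp: int = 120
    conserved_mutation_rate: float = 0.05
    background_mutation_rate: float = 0.50
    n_background_promoters: int = 400
    planted_motifs: dict[str, tuple[str, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_MOTIFS))
    phenotype_link: dict[str, tuple[str, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPE_LINK))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes <= 0 or self.replicates_per_group <= 0 or self.batches <= 0:
            raise ValueError("counts must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if sum(self.pattern_sizes.values()) > self.n_probes:
            raise ValueError("pattern sizes exceed n_probes")
        known = set(self.drugs)
        for pattern, per_drug in self.effect_profile.items():
            unknown = set(per_drug) - known
            if unknown:
                raise ValueError(
                    f"effect_profile for pattern {pattern!r} references "
                    f"unknown drugs: {sorted(unknown)}")

    def effect(self, pattern: str, drug: str, time_h: int) -> float:
        """Planted log2 effect for (pattern, drug, time); 0 if unset."""
        return self.effect_profile.get(pattern, {}).get(drug, {}).get(time_h, 0.0)

    # -- YAML round trip ------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        payload = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        # nested tuples inside dicts
        payload["planted_motifs"] = {
            k: list(v) for k, v in self.planted_motifs.items()}
        payload["phenotype_link"] = {
            k: list(v) for k, v in self.phenotype_link.items()}
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        payload = yaml.safe_load(Path(path).read_text())
        payload["diurnal_amplitude"] = tuple(payload["diurnal_amplitude"])
        payload["planted_motifs"] = {
            k: tuple(v) for k, v in payload["planted_motifs"].items()}
        payload["phenotype_link"] = {
            k: tuple(v) for k, v in payload["phenotype_link"].items()}
        # YAML stringifies integer dict keys in effect_profile
        payload["effect_profile"] = {
            p: {d: {int(t): float(e) for t, e in times.items()}
                for d, times in per_drug.items()}
            for p, per_drug in payload["effect_profile"].items()}
        return cls(**payload)


def null_config(**overrides) -> SimulationConfig:
    """Config with every drug effect removed (global-null simulation)."""
    overrides.setdefault("effect_profile", {})
    overrides.setdefault("pattern_sizes", {})
    return SimulationConfig(**overrides)


@dataclass
class GroundTruth:
    """Ledger of what was planted, for recovery tests.

    ``pattern_membership`` maps probe -> pattern label (probes absent are
    background); ``planted_inhibition`` maps (experiment id, pattern) ->
    planted percent inhibition and is filled in by the inhibitor-arm
    simulator.
    """

    pattern_membership: dict[str, str] = field(default_factory=dict)
    diurnal_probes: set[str] = field(default_factory=set)
    planted_motifs: dict[str, tuple[str, float, float]] = field(default_factory=dict)
    planted_inhibition: dict[tuple[str, str], float] = field(default_factory=dict)
    phenotype_link: dict[str, tuple[str, float, float]] = field(default_factory=dict)

    def pattern_genes(self, pattern: str) -> list[str]:
        return [g for g, p in self.pattern_membership.items() if p == pattern]

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "pattern_membership": dict(self.pattern_membership),
            "diurnal_probes": sorted(self.diurnal_probes),
            "planted_motifs": {k: list(v) for k, v in self.planted_motifs.items()},
            "planted_inhibition": {
                f"{exp}|{pat}": float(v)
                for (exp, pat), v in self.planted_inhibition.items()},
            "phenotype_link": {k: list(v) for k, v in self.phenotype_link.items()},
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GroundTruth":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            pattern_membership=payload["pattern_membership"],
            diurnal_probes=set(payload["diurnal_probes"]),
            planted_motifs={k: tuple(v) for k, v in payload["planted_motifs"].items()},
            planted_inhibition={
                tuple(k.split("|", 1)): float(v)
                for k, v in payload["planted_inhibition"].items()},
            phenotype_link={k: tuple(v) for k, v in payload["phenotype_link"].items()},
        )
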