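"""Conserved-promoter transcription-factor binding-site analysis.

The approach follows classical phylogenetic footprinting: promoter
windows (-5000..+1000 around the TSS) of a target species are aligned
to the orthologous promoter of a second species; positions covered by
an alignment window of at least 70% identity are treated as conserved;
position-weight-matrix hits whose full footprint lies in conserved
sequence are counted, capped at 50 per promoter and matrix; and a
per-pattern presence/absence Fisher test measures over-representation
of a motif in a foreground gene list against the background universe.

Coordinates are 0-based and half-open with the TSS at 0 (negative =
upstream); strands are '+'/'-'.  PWM scores are additive log2 odds with
an additive pseudocount proportional to the background frequencies
(total mass 0.8 per column); a hit's *relative score* rescales the raw
log-odds between the matrix's minimum and maximum achievable scores.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

BASES = "ACGT"
_ENC = {b: i for i, b in enumerate(BASES)}
_ENC.update({"N": 4, "-": 5})
_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")

DEFAULT_PSEUDOCOUNT = 0.8
DEFAULT_MIN_RELATIVE_SCORE = 0.80
DEFAULT_CONSERVATION_WINDOW = 50
DEFAULT_CONSERVATION_THRESHOLD = 0.70
DEFAULT_HIT_CAP = 50


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_ENC[b] for b in sequence.upper()], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence") from exc


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position frequency matrix with a log-odds scorer.

    ``counts`` is 4 x L in A, C, G, T row order.  The log-odds of
    column j for base b is ``log2(((counts[b,j] + pc*bg[b]) /
    (colsum_j + pc)) / bg[b])`` with pseudocount mass ``pc``.
    N bases contribute zero (background) log-odds.
    """

    matrix_id: str
    name: str
    counts: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 4:
            raise ValueError("counts must be 4 x L with L >= 4")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if (self.counts.sum(axis=0) == 0).any():
            raise ValueError("empty PWM column")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        colsum = self.counts.sum(axis=0)
        p = (self.counts + self.pseudocount * self.background[:, None]) / (
            colsum + self.pseudocount)
        return np.log2(p / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))

    def relative(self, raw: np.ndarray) -> np.ndarray:
        lo, hi = self.min_score, self.max_score
        return (np.asarray(raw) - lo) / (hi - lo)

    def reverse_complemented(self) -> "PWM":
        return PWM(self.matrix_id, self.name, self.counts[::-1, ::-1].copy(),
                   self.background[::-1].copy(), self.pseudocount)

    @classmethod
    def from_consensus(cls, matrix_id: str, consensus: str,
                       match_count: int = 85, total: int = 100,
                       name: str | None = None) -> "PWM":
        """Build a sharp synthetic matrix around a consensus string."""
        consensus = consensus.upper()
        other = (total - match_count) / 3.0
        counts = np.full((4, len(consensus)), other)
        for j, b in enumerate(consensus):
            counts[_ENC[b], j] = match_count
        return cls(matrix_id, name or matrix_id, counts)


@dataclass
class TfbsHit:
    """One motif occurrence; [start, end) is the TSS-relative footprint."""

    gene: str
    matrix_id: str
    strand: str
    start: int
    end: int
    score: float
    rel_score: float
    conserved: bool = False


@dataclass
class PromoterPair:
    """Aligned promoter window of a gene and its ortholog.

    Both sequences have equal aligned length over {A,C,G,T,N,-};
    ``tss`` is the TSS position in alignment coordinates.
    """

    gene: str
    target: str
    ortholog: str
    tss: int

    def __post_init__(self) -> None:
        if len(self.target) != len(self.ortholog):
            raise ValueError(f"{self.gene}: aligned lengths differ")
        if not (0 <= self.tss < len(self.target)):
            raise ValueError(f"{self.gene}: TSS outside alignment")

    @property
    def target_ungapped(self) -> str:
        return self.target.replace("-", "")

    @property
    def tss_ungapped(self) -> int:
        """TSS position in ungapped target coordinates."""
        return self.tss - self.target[: self.tss].count("-")


@dataclass
class PromoterSet:
    """Promoter pairs plus the PWM collection used to scan them."""

    pairs: dict[str, PromoterPair]
    pwms: dict[str, PWM]


# ---------------------------------------------------------------------------
# conservation masking


def conservation_mask(pair: PromoterPair,
                      window_bp: int = DEFAULT_CONSERVATION_WINDOW,
                      threshold: float = DEFAULT_CONSERVATION_THRESHOLD,
                      ) -> np.ndarray:
    """Boolean conservation mask in ungapped target coordinates.

    A target position is conserved iff some alignment window of
    ``window_bp`` columns covering it has identity >= ``threshold``
    (gaps and N count as mismatches).
    """
    t = _encode(pair.target)
    o = _encode(pair.ortholog)
    n = len(t)
    if window_bp > n:
        raise ValueError("window longer than alignment")
    match = ((t == o) & (t < 4)).astype(float)
    # identity of every window via cumulative sums
    cs = np.concatenate([[0.0], np.cumsum(match)])
    wsum = cs[window_bp:] - cs[:-window_bp]          # one per window start
    qualifies = wsum / window_bp >= threshold
    # union of qualifying windows: difference-array dilation
    covered = np.zeros(n + 1, dtype=int)
    starts = np.flatnonzero(qualifies)
    np.add.at(covered, starts, 1)
    np.add.at(covered, starts + window_bp, -1)
    aligned_mask = np.cumsum(covered[:-1]) > 0
    return aligned_mask[t != 5]  # drop gap columns of the target


# ---------------------------------------------------------------------------
# scanning


def _scores_all_offsets(enc: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Raw log-odds score of every offset of a motif along an encoded seq."""
    L = log_odds.shape[1]
    lo5 = np.vstack([log_odds, np.zeros((1, L))])  # row 4: N scores 0
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    return lo5[windows, np.arange(L)].sum(axis=1)


def scan_pwm(sequence: str, pwm: PWM,
             min_relative_score: float = DEFAULT_MIN_RELATIVE_SCORE,
             both_strands: bool = True, tss: int = 0,
             gene: str = "") -> list[TfbsHit]:
    """All motif hits with relative score >= cutoff, sorted by position.

    ``tss`` shifts reported starts to TSS-relative coordinates.
    Sequences shorter than the motif yield an empty list.
    """
    seq = sequence.upper()
    if len(seq) < pwm.length:
        return []
    enc = _encode(seq)
    if (enc == 5).any():
        raise ValueError("scan_pwm expects an ungapped sequence")
    hits: list[TfbsHit] = []
    strands = [("+", pwm.log_odds)]
    if both_strands:
        strands.append(("-", pwm.reverse_complemented().log_odds))
    for strand, lo in strands:
        raw = _scores_all_offsets(enc, lo)
        rel = pwm.relative(raw)
        for pos in np.flatnonzero(rel >= min_relative_score):
            hits.append(TfbsHit(gene=gene, matrix_id=pwm.matrix_id,
                                strand=strand, start=int(pos) - tss,
                                end=int(pos) - tss + pwm.length,
                                score=float(raw[pos]),
                                rel_score=float(rel[pos])))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def conserved_hits(pair: PromoterPair, pwm: PWM,
                   mask: np.ndarray | None = None,
                   cap: int = DEFAULT_HIT_CAP,
                   min_relative_score: float = DEFAULT_MIN_RELATIVE_SCORE,
                   both_strands: bool = True) -> list[TfbsHit]:
    """Hits whose footprint lies fully in conserved sequence, capped.

    If more than ``cap`` conserved hits are found, the top ``cap`` by
    raw score are kept (ties broken by position, then strand).  The
    returned list is sorted by position.
    """
    if mask is None:
        mask = conservation_mask(pair)
    seq = pair.target_ungapped
    tssu = pair.tss_ungapped
    hits = scan_pwm(seq, pwm, min_relative_score=min_relative_score,
                    both_strands=both_strands, tss=tssu, gene=pair.gene)
    kept = []
    for h in hits:
        s = h.start + tssu
        if mask[s: s + pwm.length].all():
            h.conserved = True
            kept.append(h)
    if len(kept) > cap:
        kept.sort(key=lambda h: (-h.score, h.start, h.strand))
        kept = kept[:cap]
    kept.sort(key=lambda h: (h.start, h.strand))
    return kept


# ---------------------------------------------------------------------------
# enrichment


@dataclass
class TfbsEnrichment:
    matrix_id: str
    fold: float          # foreground presence rate / background presence rate
    p: float             # one-sided Fisher (hypergeometric upper tail)
    k: int               # foreground genes with >= 1 conserved hit
    n: int               # foreground size
    K: int               # universe genes with >= 1 conserved hit
    N: int               # universe size
    infinite_fold: bool = False


def promoter_presence(pairs: Mapping[str, PromoterPair], pwm: PWM,
                      cap: int = DEFAULT_HIT_CAP,
                      min_relative_score: float = DEFAULT_MIN_RELATIVE_SCORE,
                      masks: Mapping[str, np.ndarray] | None = None,
                      ) -> dict[str, bool]:
    """Per-gene indicator of at least one conserved hit of ``pwm``."""
    out = {}
    for gene, pair in pairs.items():
        mask = masks.get(gene) if masks is not None else None
        out[gene] = bool(conserved_hits(pair, pwm, mask=mask, cap=cap,
                                        min_relative_score=min_relative_score))
    return out


def tfbs_enrichment(foreground: Iterable[str], background: Iterable[str],
                    presence: Mapping[str, bool], pwm_id: str = "",
                    ) -> TfbsEnrichment:
    """Motif over-representation in a foreground list vs. the universe.

    ``background`` is the gene universe and must contain the foreground.
    Fold is the ratio of presence rates; the p-value is the
    hypergeometric upper tail of drawing >= k present genes in a
    foreground of size n from a universe of N with K present.
    """
    bg = list(dict.fromkeys(background))
    fg = list(dict.fromkeys(foreground))
    missing = set(fg) - set(bg)
    if missing:
        raise ValueError(f"foreground genes outside universe: {sorted(missing)[:5]}")
    N = len(bg)
    n = len(fg)
    K = sum(bool(presence.get(g, False)) for g in bg)
    k = sum(bool(presence.get(g, False)) for g in fg)
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n else 1.0
    if K == 0:
        return TfbsEnrichment(pwm_id, float("inf") if k else 0.0, p,
                              k, n, K, N, infinite_fold=bool(k))
    fold = (k / n) / (K / N) if n else 0.0
    return TfbsEnrichment(pwm_id, fold, p, k, n, K, N)


# ---------------------------------------------------------------------------
# JASPAR text I/O (2016 dialect: ">ID NAME" then 4 bracketed count rows)


def write_jaspar(pwms: Iterable[PWM], path: str | Path) -> None:
    lines = []
    for pwm in pwms:
        lines.append(f">{pwm.matrix_id} {pwm.name}")
        for base, row in zip(BASES, pwm.counts):
            body = " ".join(f"{v:6.0f}" if float(v).is_integer() else f"{v:8.2f}"
                            for v in row)
            lines.append(f"{base}  [ {body} ]")
    Path(path).write_text("\n".join(lines) + "\n")


def read_jaspar(path: str | Path) -> dict[str, PWM]:
    """Parse JASPAR-format PFMs (via Bio.motifs) into :class:`PWM` objects."""
    from Bio import motifs as bio_motifs

    text = Path(path).read_text()
    parsed = bio_motifs.parse(_io.StringIO(text), "jaspar")
    out: dict[str, PWM] = {}
    for m in parsed:
        counts = np.array([m.counts[b] for b in BASES], dtype=float)
        out[m.matrix_id] = PWM(m.matrix_id, m.name or m.matrix_id, counts)
    return out


def hits_to_bed(hits: Iterable[TfbsHit], path: str | Path) -> None:
    """BED6 export: chrom = gene, name = matrix id, score = 1000 * relative.

    Coordinates are TSS-relative (0 = TSS, negative upstream, half-open),
    as stated in the header line.
    """
    lines = ["# coordinates: 0-based half-open, TSS at 0, upstream negative"]
    for h in hits:
        lines.append("\t".join([
            h.gene, str(h.start), str(h.end), h.matrix_id,
            str(int(round(1000 * h.rel_score))), h.strand,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")
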