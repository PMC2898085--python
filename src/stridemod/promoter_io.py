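"""Aligned promoter FASTA dialect.

Two records per gene: ``<gene>|target`` and ``<gene>|ortholog`` with
equal aligned lengths (gaps as '-').  The TSS position in alignment
coordinates is carried in the record description as ``tss=<int>``.
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tfbs import PromoterPair, PromoterSet


def write_promoters(promoters: PromoterSet | dict[str, PromoterPair],
                    path: str | Path) -> None:
    pairs = promoters.pairs if isinstance(promoters, PromoterSet) else promoters
    records = []
    for gene, pair in pairs.items():
        for role, seq in (("target", pair.target), ("ortholog", pair.ortholog)):
            records.append(SeqRecord(Seq(seq), id=f"{gene}|{role}",
                                     description=f"tss={pair.tss}"))
    SeqIO.write(records, str(path), "fasta")


def read_promoters(path: str | Path) -> dict[str, PromoterPair]:
    halves: dict[str, dict[str, str]] = {}
    tss: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene, _, role = rec.id.rpartition("|")
        if role not in ("target", "ortholog") or not gene:
            raise ValueError(f"unexpected record id {rec.id!r}")
        halves.setdefault(gene, {})[role] = str(rec.seq).upper()
        for token in rec.description.split():
            if token.startswith("tss="):
                tss[gene] = int(token[4:])
    pairs = {}
    for gene, parts in halves.items():
        if set(parts) != {"target", "ortholog"}:
            raise ValueError(f"gene {gene!r} is missing a record")
        pairs[gene] = PromoterPair(gene=gene, target=parts["target"],
                                   ortholog=parts["ortholog"],
                                   tss=tss.get(gene, 0))
    return pairs
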