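"""FASTA/FASTQ reading and writing (Biopython-backed) plus the collapsed-read
FASTA convention `>seq<i>_x<count>`."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .preprocess import UniqueRead
from .sequtils import to_dna


def read_fasta(path) -> dict[str, str]:
    return {rec.id: to_dna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> list[str]:
    return [to_dna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads, path, quality: int = 40) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read{i + 1}\n{seq}\n+\n{chr(33 + quality) * len(seq)}\n")


def write_collapsed_fasta(unique: list[UniqueRead], group: str, path) -> None:
    with open(path, "w") as fh:
        for i, u in enumerate(unique, start=1):
            if u.count(group) > 0 and u.sequence:
                fh.write(f">seq{i}_x{u.count(group)}\n{u.sequence}\n")


def read_collapsed_fasta(path, group: str) -> list[UniqueRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        count = int(rec.id.rsplit("_x", 1)[1])
        out.append(UniqueRead(to_dna(str(rec.seq)), {group: count}))
    return out


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
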