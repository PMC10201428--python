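"""Plain-text sequence and table I/O shared by the CLI and simulators."""
from __future__ import annotations

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fastq(path, reads, name_prefix: str = "read") -> None:
    """Write reads as 4-line FASTQ with constant sentinel qualities.

    No analysis stage uses base qualities, so a uniform placeholder is
    written.
    """
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{name_prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path) -> list[str]:
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]


def write_fasta(path, records) -> None:
    """Write ``(name, sequence)`` pairs as FASTA."""
    seqs = [SeqRecord(Seq(s), id=n, description="") for n, s in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
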