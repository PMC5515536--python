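"""FASTA I/O helpers (thin wrappers over Biopython)."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["read_fasta", "write_fasta"]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly multi-record, line-wrapped) FASTA file.

    Returns (id, uppercase sequence) pairs in file order.
    """
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records],
        str(path),
        "fasta",
    )
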