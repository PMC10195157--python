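"""FASTA I/O for identifier -> sequence maps.

A sequence set is a plain dict mapping a unique record identifier to a
residue string.  Headers are taken up to the first whitespace; ambiguity
codes are passed through untouched.
"""

from __future__ import annotations

import os
from typing import Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["read_fasta", "write_fasta"]


def read_fasta(path: str | os.PathLike) -> dict:
    """Read a FASTA file into an id -> sequence dict.

    Raises ``ValueError`` on duplicate identifiers or empty records.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty record {rec.id!r} in {path}")
        seqs[rec.id] = seq
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike, *, width: int = 60) -> None:
    """Write an id -> sequence map as FASTA with configurable line wrap."""
    records = [SeqRecord(Seq(s), id=str(i), description="") for i, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width or None)
        writer.write_file(records)
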