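"""Small sequence utilities shared across the pipeline.

Genomic files (FASTA) use the DNA alphabet with T; RNA-level processing
(folding, duplex geometry) uses U.  Conversion happens at module
boundaries via :func:`to_rna` / :func:`to_dna`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_DNA_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")
_RNA_COMPLEMENT = str.maketrans("ACGUTacgut", "UGCAAugcaa")

VALID_BASES = frozenset("ACGTU")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    """Reverse complement in the alphabet of the input (T stays T, U stays U)."""
    if "U" in seq or "u" in seq:
        return seq.translate(_RNA_COMPLEMENT)[::-1]
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> ordered {id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    SeqIO.write(recs, str(path), "fasta-2line")


def iter_reads(path: str | Path) -> Iterator[str]:
    """Yield read sequences from FASTA or FASTQ (gz accepted), format by suffix."""
    import gzip

    p = str(path)
    opener = gzip.open if p.endswith(".gz") else open
    stem = p[:-3] if p.endswith(".gz") else p
    fmt = "fastq" if stem.endswith((".fq", ".fastq")) else "fasta"
    with opener(p, "rt") as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield str(rec.seq).upper()
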