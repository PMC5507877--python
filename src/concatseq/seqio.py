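"""FASTA/FASTQ input/output and elementary nucleotide-string operations.

Conventions used throughout the package:

* coordinates are 0-based, half-open;
* sequences are upper-case strings over the alphabet ``{A, C, G, T, N}``;
* qualities are Sanger-scaled (ASCII offset 33) strings of the same length
  as the sequence.

Parsing is delegated to :mod:`Bio.SeqIO`; writing is done by hand so that
output is byte-stable (4-line FASTQ, unwrapped 2-line FASTA) and round-trips
exactly through the reader.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Union

from Bio import SeqIO as _BioSeqIO

PathLike = Union[str, "object"]

VALID_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FORWARD = "forward"
REVCOMP = "revcomp"


@dataclass
class SeqRecord:
    """A named nucleotide sequence with optional per-base qualities."""

    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: quality string length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _open(path: PathLike, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastx(path: PathLike, format: str) -> Iterator[SeqRecord]:
    """Stream records from a FASTA or FASTQ file.

    Sequences are upper-cased; ``N`` is preserved.  Malformed records raise
    ``ValueError`` naming the 0-based record index at which parsing failed.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}; expected 'fasta' or 'fastq'")
    with _open(path) as handle:
        parser = _BioSeqIO.parse(handle, format)
        index = 0
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(
                    f"malformed {format} record at index {index} in {path}: {exc}"
                ) from exc
            qual = None
            if format == "fastq":
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
            yield SeqRecord(id=rec.id, seq=str(rec.seq).upper(), qual=qual)
            index += 1


def write_fastx(records: Iterable[SeqRecord], path: PathLike, format: str) -> int:
    """Write records as 4-line FASTQ or unwrapped FASTA; returns the count.

    FASTQ output requires every record to carry qualities and a non-empty
    sequence.  An empty record stream produces an empty file.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}; expected 'fasta' or 'fastq'")
    n = 0
    with _open(path, "wt") as out:
        for rec in records:
            if format == "fastq":
                if rec.qual is None:
                    raise ValueError(
                        f"record {rec.id!r} has no qualities; required for FASTQ"
                    )
                if not rec.seq:
                    raise ValueError(f"record {rec.id!r}: empty sequence in FASTQ")
                out.write(f"@{rec.id}\n{rec.seq}\n+\n{rec.qual}\n")
            else:
                out.write(f">{rec.id}\n{rec.seq}\n")
            n += 1
    return n


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over ``{A,C,G,T,N}`` (N maps to N)."""
    bad = set(seq) - VALID_ALPHABET
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]
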