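"""Sequence records, ORF calling, translation and FASTA/GenBank I/O.

Every downstream signal works on :class:`SequenceRecord` objects: a named
nucleotide sequence with optional CDS annotations (0-based half-open,
strand +1/-1 on the forward axis) and an optional host label.  Input is
normalised on ingest: lowercase is uppercased and U is mapped to T, so the
working alphabet is always {A, C, G, T, N}.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq

from ._kmers import InvalidAlphabetError, encode

__all__ = [
    "SequenceRecord",
    "Orf",
    "InvalidAlphabetError",
    "FastaFormatError",
    "reverse_complement",
    "find_orfs",
    "six_frame_translate",
    "translate",
    "read_fasta",
    "write_fasta",
    "read_genbank",
]

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Raised for empty FASTA files or duplicate record identifiers."""


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; raises on any other character.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    encode(seq)  # alphabet validation (accepts lowercase, rejects others)
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass
class SequenceRecord:
    """A named nucleotide sequence with optional CDS annotations.

    ``cds`` entries are (start, end, strand) with 0-based half-open
    coordinates on the forward strand; strand is +1 or -1.  Each CDS span
    must be divisible by 3 and lie within the sequence.
    """

    id: str
    seq: str
    cds: list[tuple[int, int, int]] | None = None
    host_label: str | None = None

    def __post_init__(self):
        self.seq = _normalize(self.seq)
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        encode(self.seq)  # alphabet check
        if self.cds is not None:
            for start, end, strand in self.cds:
                if strand not in (1, -1):
                    raise ValueError(f"record {self.id!r}: CDS strand must be +1/-1")
                if not (0 <= start < end <= len(self.seq)):
                    raise ValueError(f"record {self.id!r}: CDS ({start},{end}) out of bounds")
                if (end - start) % 3:
                    raise ValueError(f"record {self.id!r}: CDS length not divisible by 3")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Orf:
    """An open reading frame: half-open forward-strand coordinates plus
    the translated peptide (stop codon removed)."""

    start: int
    end: int
    strand: int
    peptide: str


def translate(seq: str) -> str:
    """Translate a nucleotide string with the standard code; stops are
    rendered as '*', partial trailing codons dropped, N-codons as 'X'."""
    n = len(seq) - len(seq) % 3
    if n == 0:
        return ""
    return str(Seq(_normalize(seq)[:n]).translate())


def six_frame_translate(seq: str) -> list[str]:
    """Peptides for frames +0,+1,+2 then -0,-1,-2 (reverse complement)."""
    seq = _normalize(seq)
    rc = reverse_complement(seq)
    return [translate(s[f:]) for s in (seq, rc) for f in range(3)]


def _scan_strand(seq: str, min_codons: int) -> list[tuple[int, int]]:
    """Start/stop spans (half-open, incl. stop codon) on one strand."""
    out = []
    n = len(seq)
    for frame in range(3):
        start = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if start is not None and (i - start) // 3 >= min_codons:
                    out.append((start, i + 3))
                start = None
            elif start is None and codon in START_CODONS:
                start = i
    return out


def find_orfs(rec: SequenceRecord | str, min_codons: int = 60) -> list[Orf]:
    """Call ORFs on both strands.

    An ORF starts at the leftmost start codon (ATG/GTG/TTG) after the
    previous in-frame stop, ends at the first in-frame stop, and encodes
    at least ``min_codons`` amino acids.  Reverse-strand ORFs are reported
    with forward-axis coordinates.
    """
    if min_codons < 2:
        raise ValueError("min_codons must be >= 2")
    seq = rec.seq if isinstance(rec, SequenceRecord) else _normalize(rec)
    orfs = []
    for start, end in _scan_strand(seq, min_codons):
        orfs.append(Orf(start, end, 1, translate(seq[start:end])[:-1]))
    rc = reverse_complement(seq)
    n = len(seq)
    for start, end in _scan_strand(rc, min_codons):
        orfs.append(Orf(n - end, n - start, -1, translate(rc[start:end])[:-1]))
    orfs.sort(key=lambda o: (o.start, o.end, -o.strand))
    return orfs


def orf_peptides(rec: SequenceRecord, min_codons: int = 60) -> list[tuple[str, str]]:
    """(id, peptide) pairs from annotated CDS if present, else called ORFs.

    CDS peptides are translated strand-resolved with the trailing stop
    (if encoded) removed.
    """
    out = []
    if rec.cds:
        for i, (start, end, strand) in enumerate(rec.cds):
            sub = rec.seq[start:end]
            if strand == -1:
                sub = reverse_complement(sub)
            pep = translate(sub)
            if pep.endswith("*"):
                pep = pep[:-1]
            if pep:
                out.append((f"{rec.id}|cds{i}", pep))
    else:
        for i, orf in enumerate(find_orfs(rec, min_codons)):
            out.append((f"{rec.id}|orf{i}", orf.peptide))
    return out


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into SequenceRecords.

    Sequences are uppercased and U is mapped to T.  Empty files and
    duplicate identifiers raise :class:`FastaFormatError`.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq)))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_genbank(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read GenBank-flavoured records, keeping CDS features and the
    source /host qualifier (used as the record's host label)."""
    records = []
    for rec in SeqIO.parse(str(path), "genbank"):
        cds = []
        host = None
        for feat in rec.features:
            if feat.type == "source":
                vals = feat.qualifiers.get("host")
                if vals:
                    host = vals[0]
            elif feat.type == "CDS":
                for part in feat.location.parts:
                    start, end = int(part.start), int(part.end)
                    if (end - start) % 3 == 0 and end > start:
                        cds.append((start, end, 1 if part.strand != -1 else -1))
        records.append(
            SequenceRecord(id=rec.id, seq=str(rec.seq), cds=cds or None, host_label=host)
        )
    if not records:
        raise FastaFormatError(f"no GenBank records found in {path}")
    return records
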