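"""Sequence and alignment data model, FASTA I/O and reading-frame checks.

The distance and tree machinery downstream works on pre-aligned,
equal-length gapped DNA sequences (one alignment per marker: the
mitochondrial cox1 barcode and the ribosomal ITS2 and 28S fragments).
This module provides the in-memory containers, plain-FASTA round-trip
I/O, and the translation sanity check used on mitochondrial barcodes:
translating each forward frame under the echinoderm/flatworm
mitochondrial code (NCBI translation table 9) and flagging internal
stop codons, which would indicate a pseudogene or frameshifted read.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence as TypingSequence

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "Marker",
    "Sequence",
    "SequenceCollection",
    "Alignment",
    "GeneticCode",
    "FrameReport",
    "SeqCoreError",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "scan_reading_frames",
]

MARKERS = ("cox1", "ITS2", "28S", "other")
Marker = str

# IUPAC nucleotide one-letter codes, gap, and missing.
_IUPAC_AMBIGUITY = set("RYSWKMBDHV")
_ALPHABET = set("ACGTUN-") | _IUPAC_AMBIGUITY
#: Characters treated as missing data under pairwise deletion: gaps, N and
#: every ambiguity code (the MEGA-style joint "Gaps/Missing Data" treatment).
MISSING_CHARS = frozenset("N-") | frozenset(_IUPAC_AMBIGUITY)


class SeqCoreError(ValueError):
    """Invalid sequence/alignment input."""


class FastaParseError(SeqCoreError):
    """Malformed FASTA input."""


@dataclass(frozen=True)
class Sequence:
    """A single named nucleotide sequence.

    Residues are stored uppercase with U normalized to T, so ribosomal
    markers sequenced as RNA-coding regions are handled in DNA space.
    """

    id: str
    residues: str
    marker: Marker = "other"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqCoreError("sequence id must be non-empty")
        if not self.residues:
            raise SeqCoreError(f"sequence {self.id!r}: residues must be non-empty")
        if self.marker not in MARKERS:
            raise SeqCoreError(f"sequence {self.id!r}: unknown marker {self.marker!r}")
        norm = self.residues.upper().replace("U", "T")
        bad = set(norm) - _ALPHABET
        if bad:
            raise SeqCoreError(
                f"sequence {self.id!r}: illegal characters {sorted(bad)!r}"
            )
        object.__setattr__(self, "residues", norm)

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        """Residues with alignment gaps removed."""
        return self.residues.replace("-", "")


class SequenceCollection:
    """An ordered set of sequences with unique ids, possibly of unequal length."""

    def __init__(self, sequences: TypingSequence[Sequence], marker: Marker = "other"):
        seqs = list(sequences)
        if not seqs:
            raise SeqCoreError("collection must contain at least one sequence")
        ids = [s.id for s in seqs]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise SeqCoreError(f"duplicate sequence ids: {sorted(dupes)}")
        self.sequences: tuple[Sequence, ...] = tuple(seqs)
        self.marker = marker

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[Sequence]:
        return iter(self.sequences)

    def __getitem__(self, key: int | str) -> Sequence:
        if isinstance(key, str):
            for s in self.sequences:
                if s.id == key:
                    return s
            raise KeyError(key)
        return self.sequences[key]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.sequences)

    @property
    def is_alignment_capable(self) -> bool:
        """True when all members share one length and there are >= 2 of them."""
        lengths = {len(s) for s in self.sequences}
        return len(lengths) == 1 and len(self.sequences) >= 2

    def to_alignment(self) -> "Alignment":
        if not self.is_alignment_capable:
            raise SeqCoreError(
                "sequences are not alignment-capable (unequal lengths or < 2 records)"
            )
        return Alignment(self.sequences, marker=self.marker)


class Alignment(SequenceCollection):
    """An equal-length gapped multiple alignment (>= 2 sequences)."""

    def __init__(self, sequences: TypingSequence[Sequence], marker: Marker = "other"):
        super().__init__(sequences, marker=marker)
        lengths = {len(s) for s in self.sequences}
        if len(self.sequences) < 2:
            raise SeqCoreError("alignment requires at least 2 sequences")
        if len(lengths) != 1:
            raise SeqCoreError(f"alignment members have unequal lengths: {sorted(lengths)}")
        self.length: int = lengths.pop()

    def column(self, i: int) -> str:
        return "".join(s.residues[i] for s in self.sequences)


def read_fasta(path: str | os.PathLike, marker: Marker = "other") -> SequenceCollection:
    """Read a plain multi-FASTA file.

    Returns a :class:`SequenceCollection` (check ``is_alignment_capable`` /
    call ``to_alignment()``); records keep file order, headers are split
    into id and description, the description is preserved but otherwise
    ignored.
    """
    records = []
    try:
        parsed = list(SeqIO.parse(os.fspath(path), "fasta"))
    except Exception as exc:  # pragma: no cover - Biopython is permissive
        raise FastaParseError(f"{path}: {exc}") from exc
    if not parsed:
        raise FastaParseError(f"{path}: no FASTA records found")
    for i, rec in enumerate(parsed):
        if not rec.id:
            raise FastaParseError(f"{path}: record {i} has an empty header")
        if len(rec.seq) == 0:
            raise FastaParseError(f"{path}: record {i} ({rec.id!r}) is empty")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        try:
            records.append(
                Sequence(id=rec.id, residues=str(rec.seq), marker=marker, description=desc)
            )
        except SeqCoreError as exc:
            raise FastaParseError(f"{path}: record {i}: {exc}") from exc
    return SequenceCollection(records, marker=marker)


def write_fasta(seqs: SequenceCollection | TypingSequence[Sequence],
                path: str | os.PathLike, wrap: int = 70) -> None:
    """Write sequences as plain FASTA, wrapped at ``wrap`` columns.

    Round-trip property: ``read_fasta(write_fasta(S))`` reproduces ids and
    residues exactly, in input order. Duplicate ids fail before any output
    is written.
    """
    seqs = list(seqs)
    if not seqs:
        raise SeqCoreError("refusing to write an empty FASTA file")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise SeqCoreError("duplicate sequence ids; not writing")
    with open(path, "w") as fh:
        for s in seqs:
            header = f">{s.id}" + (f" {s.description}" if s.description else "")
            fh.write(header + "\n")
            for start in range(0, len(s.residues), wrap):
                fh.write(s.residues[start:start + wrap] + "\n")


@dataclass(frozen=True)
class GeneticCode:
    """A complete 64-codon translation table; stops are mapped to ``*``."""

    table_id: int
    codon_map: dict = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.codon_map) != 64:
            raise SeqCoreError(
                f"genetic code {self.table_id}: codon map covers "
                f"{len(self.codon_map)} codons, expected 64"
            )

    @classmethod
    def from_ncbi(cls, table_id: int) -> "GeneticCode":
        """Build from Biopython's embedded copy of the NCBI tables.

        Table 9 (echinoderm/flatworm mitochondrial) is the one used for
        barcode frame checks here; it reassigns AGA/AGG to Ser, AAA to
        Asn and TGA to Trp relative to the standard code.
        """
        tbl = CodonTable.unambiguous_dna_by_id[table_id]
        codon_map = dict(tbl.forward_table)
        for stop in tbl.stop_codons:
            codon_map[stop] = "*"
        return cls(table_id=table_id, codon_map=codon_map)

    def is_stop(self, codon: str) -> bool:
        return self.codon_map.get(codon.upper()) == "*"

    def translate(self, seq: str) -> str:
        """Translate in frame 0; codons with ambiguity/missing become X."""
        out = []
        for i in range(0, len(seq) - 2, 3):
            out.append(self.codon_map.get(seq[i:i + 3].upper(), "X"))
        return "".join(out)


@dataclass(frozen=True)
class FrameReport:
    """Internal-stop-codon scan of the forward (and optionally reverse) frames."""

    sequence_id: str
    table_id: int
    #: frame offset -> 0-based codon indices of internal stop codons
    internal_stops: dict
    scanned_reverse: bool = False

    @property
    def stop_counts(self) -> dict:
        return {f: len(v) for f, v in self.internal_stops.items()}

    @property
    def has_open_frame(self) -> bool:
        """True when at least one scanned frame is free of internal stops."""
        return any(len(v) == 0 for v in self.internal_stops.values())


_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHV-", "TGCAANYRSWMKVHDB-")


def reverse_complement(residues: str) -> str:
    return residues.upper().translate(_COMPLEMENT)[::-1]


def scan_reading_frames(seq: Sequence, code: GeneticCode,
                        include_reverse: bool = False) -> FrameReport:
    """Count internal stop codons in each forward reading frame.

    Gaps are stripped first. A stop in the final (possibly partial) codon
    of a frame is terminal, not internal, and is not counted. Codons
    containing ambiguity codes or N are never counted as stops. Deposited
    barcodes are assumed to be in coding orientation, so reverse frames
    are only scanned on request.
    """
    ungapped = seq.ungapped()
    if len(ungapped) < 3:
        raise SeqCoreError(
            f"sequence {seq.id!r}: fewer than 3 residues after gap removal"
        )
    strands = [("", ungapped)]
    if include_reverse:
        strands.append(("rev", reverse_complement(ungapped)))
    internal: dict = {}
    for prefix, residues in strands:
        for frame in range(3):
            codons = [residues[i:i + 3]
                      for i in range(frame, len(residues) - 2, 3)]
            stops = [i for i, c in enumerate(codons[:-1]) if code.is_stop(c)]
            key = f"{prefix}{frame}" if prefix else frame
            internal[key] = stops
    return FrameReport(sequence_id=seq.id, table_id=code.table_id,
                       internal_stops=internal, scanned_reverse=include_reverse)
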