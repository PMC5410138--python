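"""FASTA input/output, reverse complement and six-frame translation.

Nucleotide assemblies are screened against protein profiles, so every
contig is translated in all six reading frames with the standard genetic
code (NCBI translation table 1).  Stop codons split each frame into
maximal stop-free peptide segments, and every segment keeps a coordinate
mapping back to the forward strand of its source contig so that hits can
be reported in nucleotide space.

Conventions
-----------
* Coordinates are 1-based and inclusive, always on the forward strand.
* Frames are numbered +1/+2/+3 for offsets 0..2 on the forward strand and
  -1/-2/-3 for offsets 0..2 on the reverse complement.
* IUPAC ambiguity codes other than N are normalized to N on input; codons
  containing N translate to X.
* Peptide segments shorter than ``min_peptide_len`` (default 20 aa) are
  discarded; pass 1 to keep everything.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from Bio.Data import CodonTable

DNA = "dna"
PROTEIN = "protein"

_DNA_CHARS = frozenset("ACGTN")
_PROTEIN_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYX*")
# IUPAC nucleotide ambiguity codes collapsed to the single wildcard N.
_AMBIG_TO_N = str.maketrans({c: "N" for c in "RYSWKMBDHVU"})
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_TABLE1 = CodonTable.unambiguous_dna_by_id[1]
_CODON = dict(_TABLE1.forward_table)
_CODON.update({c: "*" for c in _TABLE1.stop_codons})

FRAMES = (1, 2, 3, -1, -2, -3)


class FastaParseError(ValueError):
    """Malformed FASTA input; message names the offending line."""


class AlphabetError(TypeError):
    """Sequence used with the wrong alphabet."""


@dataclass
class SequenceRecord:
    """A single FASTA record over a declared alphabet.

    ``id`` is the first whitespace-delimited token of the header;
    ``description`` is the remainder (possibly empty).
    """

    id: str
    residues: str
    alphabet: str = DNA
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        residues = self.residues.upper()
        if self.alphabet == DNA:
            residues = residues.translate(_AMBIG_TO_N)
            bad = set(residues) - _DNA_CHARS
        elif self.alphabet == PROTEIN:
            bad = set(residues) - _PROTEIN_CHARS
        else:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if bad:
            raise AlphabetError(
                f"sequence {self.id!r} contains characters {sorted(bad)} "
                f"illegal for alphabet {self.alphabet!r}"
            )
        self.residues = residues

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class TranslatedFrame:
    """One stop-free peptide segment from a six-frame translation.

    ``nt_start``/``nt_end`` are 1-based inclusive forward-strand
    coordinates of the codons encoding ``peptide`` on the source contig;
    for negative frames the interval still refers to the forward strand.
    ``segment_index`` is the 0-based ordinal of the segment within its
    frame, assigned before any minimum-length filtering.
    """

    contig_id: str
    frame: int
    peptide: str
    nt_start: int
    nt_end: int
    segment_index: int
    contig_length: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        if self.frame not in FRAMES:
            raise ValueError(f"invalid frame {self.frame}")
        if "*" in self.peptide or not self.peptide:
            raise ValueError("peptide must be non-empty and stop-free")
        if self.nt_end - self.nt_start + 1 != 3 * len(self.peptide):
            raise ValueError(
                f"{self.contig_id} frame {self.frame}: nucleotide span "
                f"{self.nt_start}-{self.nt_end} does not cover "
                f"{len(self.peptide)} codons"
            )
        if self.nt_start < 1 or (self.contig_length and self.nt_end > self.contig_length):
            raise ValueError("segment extends outside its contig")

    @property
    def provenance_id(self) -> str:
        return (
            f"{self.contig_id}|frame={self.frame:+d}|seg={self.segment_index}"
            f"|{self.nt_start}-{self.nt_end}"
        )


def _iter_fasta(handle: io.TextIOBase):
    """Yield (header, residue-string, header-line-number) triples.

    Strict: rejects residue data before the first header and records
    with no residues at all.
    """
    header = None
    header_line = 0
    chunks: list[str] = []
    for lineno, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                if not chunks:
                    raise FastaParseError(
                        f"line {header_line}: record {header.split()[0]!r} has no sequence"
                    )
                yield header, "".join(chunks), header_line
            header = line[1:].strip()
            if not header:
                raise FastaParseError(f"line {lineno}: empty FASTA header")
            header_line = lineno
            chunks = []
        else:
            if header is None:
                raise FastaParseError(f"line {lineno}: sequence data before first '>' header")
            chunks.append(line)
    if header is not None:
        if not chunks:
            raise FastaParseError(
                f"line {header_line}: record {header.split()[0]!r} has no sequence"
            )
        yield header, "".join(chunks), header_line


def read_fasta(path, alphabet: str = DNA) -> list[SequenceRecord]:
    """Read a (multi-record, possibly line-wrapped) FASTA file.

    Order is preserved; an empty file yields an empty list.  Malformed
    input raises :class:`FastaParseError` naming the line.
    """
    records = []
    with open(path) as handle:
        for header, residues, lineno in _iter_fasta(handle):
            parts = header.split(None, 1)
            try:
                records.append(
                    SequenceRecord(
                        id=parts[0],
                        residues=residues,
                        alphabet=alphabet,
                        description=parts[1] if len(parts) > 1 else "",
                    )
                )
            except (ValueError, AlphabetError) as exc:
                if isinstance(exc, AlphabetError):
                    raise FastaParseError(f"line {lineno}: {exc}") from exc
                raise FastaParseError(f"line {lineno}: {exc}") from exc
    return records


def write_fasta(records, path, line_width: int = 60) -> None:
    """Write records as FASTA, wrapping residues at ``line_width``."""
    if line_width < 1:
        raise ValueError("line_width must be positive")
    with open(path, "w") as handle:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            handle.write(f">{header}\n")
            res = rec.residues
            for i in range(0, len(res), line_width):
                handle.write(res[i : i + line_width] + "\n")


def reverse_complement(dna: SequenceRecord) -> SequenceRecord:
    """Watson-Crick reverse complement; an involution on DNA records."""
    if dna.alphabet != DNA:
        raise AlphabetError("reverse_complement requires a DNA record")
    return SequenceRecord(
        id=dna.id,
        residues=dna.residues.translate(_COMPLEMENT)[::-1],
        alphabet=DNA,
        description=dna.description,
    )


def _translate_codons(seq: str) -> str:
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        out.append("X" if "N" in codon else _CODON[codon])
    return "".join(out)


def translate_frame(dna: SequenceRecord, frame: int, min_peptide_len: int = 20) -> list[TranslatedFrame]:
    """Translate one reading frame into stop-delimited peptide segments."""
    if dna.alphabet != DNA:
        raise AlphabetError("translate_frame requires a DNA record")
    if frame not in FRAMES:
        raise ValueError(f"frame must be one of {FRAMES}, got {frame}")
    L = len(dna)
    strand_seq = dna.residues if frame > 0 else dna.residues.translate(_COMPLEMENT)[::-1]
    offset = abs(frame) - 1
    peptide_run = _translate_codons(strand_seq[offset:])
    segments: list[TranslatedFrame] = []
    seg_index = 0
    start_codon = 0  # codon index where current segment starts
    for run in peptide_run.split("*"):
        if run:
            # codon interval [start_codon, start_codon + len(run)) on this strand
            s = offset + 3 * start_codon + 1
            e = offset + 3 * (start_codon + len(run))
            if frame > 0:
                nt_start, nt_end = s, e
            else:
                nt_start, nt_end = L - e + 1, L - s + 1
            if len(run) >= min_peptide_len:
                segments.append(
                    TranslatedFrame(
                        contig_id=dna.id,
                        frame=frame,
                        peptide=run,
                        nt_start=nt_start,
                        nt_end=nt_end,
                        segment_index=seg_index,
                        contig_length=L,
                    )
                )
            seg_index += 1
        start_codon += len(run) + 1  # skip the stop codon
    return segments


def six_frame_translate(dna: SequenceRecord, min_peptide_len: int = 20) -> list[TranslatedFrame]:
    """All six reading frames, ordered by (frame, segment_index)."""
    out: list[TranslatedFrame] = []
    for frame in FRAMES:
        out.extend(translate_frame(dna, frame, min_peptide_len=min_peptide_len))
    return out


def translated_records(frames: list[TranslatedFrame]) -> list[SequenceRecord]:
    """Protein records whose ids encode the provenance of each segment."""
    return [
        SequenceRecord(id=f.provenance_id, residues=f.peptide, alphabet=PROTEIN)
        for f in frames
    ]
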