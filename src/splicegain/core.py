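"""Core domain types and coordinate conventions.

All internal coordinates are 0-based, half-open ``[start, end)`` on the
forward genomic strand; GFF3 I/O converts at the boundary (see
:mod:`splicegain.io`).  Transcript exons are stored in genomic order;
transcription order is derived from the strand at use sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from Bio.Seq import Seq

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str) -> str:
    """Translate an mRNA-sense sequence codon by codon.

    A codon containing ``N`` translates to ``X`` and never counts as a
    stop.  Stops are rendered as ``*``; a trailing partial codon is
    dropped.
    """
    n = len(seq) - len(seq) % 3
    return str(Seq(seq[:n]).translate())


def first_stop_codon(seq: str, frame_start: int = 0) -> int | None:
    """Return the index of the first base of the first in-frame stop
    codon in ``seq`` scanning from ``frame_start``, or None."""
    for i in range(frame_start, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return i
    return None


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval with a strand."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class GenomeSequence:
    """A single contig of genome sequence over {A, C, G, T, N}."""

    contig_name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"contig {self.contig_name} is empty")
        bad = set(self.sequence.upper()) - VALID_BASES
        if bad:
            raise ValidationError(
                f"contig {self.contig_name} contains invalid bases {sorted(bad)}"
            )
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Return exactly ``end - start`` bases; bounds are checked."""
        if start < 0 or end > len(self.sequence) or start >= end:
            raise ValidationError(
                f"[{start}, {end}) out of bounds for contig "
                f"{self.contig_name} of length {len(self.sequence)}"
            )
        return self.sequence[start:end]


@dataclass(frozen=True)
class DomainAnnotation:
    """A named protein domain in 1-based inclusive amino-acid coordinates."""

    name: str
    aa_start: int
    aa_end: int

    def __post_init__(self) -> None:
        if not (1 <= self.aa_start <= self.aa_end):
            raise ValidationError(
                f"domain {self.name}: invalid aa interval "
                f"[{self.aa_start}, {self.aa_end}]"
            )


@dataclass(frozen=True)
class JunctionCountRecord:
    """Junction read counts supporting inclusion vs skipping of one event
    in one sample."""

    event_id: str
    sample_id: str
    inclusion_counts: tuple[int, ...]
    skipping_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "inclusion_counts", tuple(self.inclusion_counts))
        object.__setattr__(self, "skipping_counts", tuple(self.skipping_counts))
        if not self.inclusion_counts or not self.skipping_counts:
            raise ValidationError(
                f"{self.event_id}/{self.sample_id}: need at least one junction "
                "on each side"
            )
        if any(c < 0 for c in self.inclusion_counts + self.skipping_counts):
            raise ValidationError(
                f"{self.event_id}/{self.sample_id}: negative junction count"
            )


@dataclass(frozen=True)
class TranscriptModel:
    """Ordered exon chain plus CDS boundaries for one transcript.

    ``cds_start``/``cds_end`` are genomic 0-based half-open boundaries of
    the full coding span (including the stop codon), irrespective of
    strand.
    """

    transcript_id: str
    gene_id: str
    intervals: tuple[GenomicInterval, ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(self.intervals))
        if not self.intervals:
            raise ValidationError(f"{self.transcript_id}: no exons")
        contig = self.intervals[0].contig
        strand = self.intervals[0].strand
        for iv in self.intervals:
            if iv.contig != contig or iv.strand != strand:
                raise ValidationError(
                    f"{self.transcript_id}: exons on mixed contigs/strands"
                )
        for a, b in zip(self.intervals, self.intervals[1:]):
            if a.end > b.start:
                raise ValidationError(
                    f"{self.transcript_id}: exons overlap or are unsorted "
                    f"({a.start}-{a.end} vs {b.start}-{b.end})"
                )
        if not (self.cds_start < self.cds_end):
            raise ValidationError(f"{self.transcript_id}: empty CDS span")
        if not self._position_in_exons(self.cds_start) or not self._position_in_exons(
            self.cds_end - 1
        ):
            raise ValidationError(
                f"{self.transcript_id}: CDS boundaries fall outside exons"
            )

    def _position_in_exons(self, pos: int) -> bool:
        return any(iv.start <= pos < iv.end for iv in self.intervals)

    @property
    def contig(self) -> str:
        return self.intervals[0].contig

    @property
    def strand(self) -> str:
        return self.intervals[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.contig, self.intervals[0].start, self.intervals[-1].end, self.strand
        )

    @property
    def spliced_length(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def exons_transcription_order(self) -> tuple[GenomicInterval, ...]:
        return self.intervals if self.strand == "+" else self.intervals[::-1]

    def introns(self) -> tuple[GenomicInterval, ...]:
        """Introns in genomic order (empty for single-exon transcripts)."""
        return tuple(
            GenomicInterval(self.contig, a.end, b.start, self.strand)
            for a, b in zip(self.intervals, self.intervals[1:])
        )

    def genomic_to_spliced(self, pos: int) -> int:
        """Map an exonic genomic position to its 0-based coordinate on the
        spliced (mRNA-sense) transcript."""
        offset = 0
        for iv in self.exons_transcription_order():
            if iv.start <= pos < iv.end:
                if self.strand == "+":
                    return offset + (pos - iv.start)
                return offset + (iv.end - 1 - pos)
            offset += iv.length
        raise ValidationError(
            f"{self.transcript_id}: position {pos} is not exonic"
        )

    def spliced_to_genomic(self, pos: int) -> int:
        """Inverse of :meth:`genomic_to_spliced`."""
        offset = 0
        for iv in self.exons_transcription_order():
            if offset <= pos < offset + iv.length:
                if self.strand == "+":
                    return iv.start + (pos - offset)
                return iv.end - 1 - (pos - offset)
            offset += iv.length
        raise ValidationError(
            f"{self.transcript_id}: spliced position {pos} out of range"
        )

    def exon_spliced_spans(self) -> tuple[tuple[int, int], ...]:
        """Half-open spliced-coordinate spans of the exons, transcription
        order."""
        spans = []
        offset = 0
        for iv in self.exons_transcription_order():
            spans.append((offset, offset + iv.length))
            offset += iv.length
        return tuple(spans)

    def last_junction_spliced_position(self) -> int | None:
        """Spliced coordinate of the final exon-exon junction, or None for
        single-exon transcripts."""
        if len(self.intervals) < 2:
            return None
        return self.spliced_length - self.exons_transcription_order()[-1].length

    def cds_spliced_span(self) -> tuple[int, int]:
        """Spliced-coordinate half-open span of the CDS."""
        if self.strand == "+":
            s = self.genomic_to_spliced(self.cds_start)
            e = self.genomic_to_spliced(self.cds_end - 1) + 1
        else:
            s = self.genomic_to_spliced(self.cds_end - 1)
            e = self.genomic_to_spliced(self.cds_start) + 1
        return s, e

    def with_exons(self, intervals: Iterable[GenomicInterval]) -> "TranscriptModel":
        return replace(self, intervals=tuple(intervals))


def spliced_sequence(t: TranscriptModel, g: GenomeSequence) -> str:
    """Concatenate exon sequences in transcription order.

    Minus-strand transcripts are reverse-complemented so the result is
    always mRNA-sense.  Length equals the sum of exon lengths.
    """
    if t.contig != g.contig_name:
        raise ValidationError(
            f"{t.transcript_id}: contig {t.contig} not in genome "
            f"({g.contig_name})"
        )
    parts = [g.fetch(iv.start, iv.end) for iv in t.intervals]
    seq = "".join(parts)
    if t.strand == "-":
        seq = reverse_complement(seq)
    return seq


def coding_sequence(t: TranscriptModel, g: GenomeSequence) -> str:
    """mRNA-sense CDS of ``t`` (start codon through stop codon)."""
    s, e = t.cds_spliced_span()
    return spliced_sequence(t, g)[s:e]


def validate_canonical_cds(t: TranscriptModel, g: GenomeSequence) -> str:
    """Check that the annotated CDS begins ATG, is a multiple of 3, and
    ends at a stop codon; returns the CDS sequence."""
    cds = coding_sequence(t, g)
    if len(cds) % 3 != 0:
        raise ValidationError(
            f"{t.transcript_id}: CDS length {len(cds)} not a multiple of 3"
        )
    if not cds.startswith("ATG"):
        raise ValidationError(f"{t.transcript_id}: CDS does not start with ATG")
    if cds[-3:] not in STOP_CODONS:
        raise ValidationError(f"{t.transcript_id}: CDS does not end at a stop codon")
    internal = first_stop_codon(cds[:-3])
    if internal is not None:
        raise ValidationError(
            f"{t.transcript_id}: internal stop codon at CDS offset {internal}"
        )
    return cds
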