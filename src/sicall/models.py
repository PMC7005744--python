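"""Core genomic domain types shared across the pipeline.

All coordinates are 0-based half-open on the forward genomic strand;
readers and writers for 1-based formats (GTF, STAR SJ.out.tab) convert
at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptModel:
    """A transcript: ordered exons plus optional CDS anchors.

    ``exons`` are stored in transcription (5'->3') order, so on the minus
    strand genomic coordinates decrease along the list.  ``cds_start`` is
    the 0-based genomic coordinate of the first base of the start codon;
    ``cds_end`` the 0-based genomic coordinate of the first base of the
    stop codon (both optional).
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        strands = {e.strand for e in self.exons}
        if len(strands) != 1:
            raise ValueError(
                f"transcript {self.transcript_id} mixes strands {sorted(strands)}"
            )
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValueError(
                f"transcript {self.transcript_id} spans chromosomes {sorted(chroms)}"
            )
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"transcript {self.transcript_id} has overlapping exons"
                )
        # normalise to transcription order
        self.exons = genomic if self.strand == "+" else genomic[::-1]

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def exons_genomic(self) -> list[GenomicInterval]:
        """Exons in ascending genomic coordinate order."""
        return sorted(self.exons, key=lambda e: e.start)

    def introns(self) -> list[GenomicInterval]:
        """Implied introns, ascending genomic order."""
        ex = self.exons_genomic
        out = []
        for a, b in zip(ex, ex[1:]):
            out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out


#: splice junction key: (chrom, donor-side genomic coord, acceptor-side
#: genomic coord) with donor < acceptor in genomic coordinates (i.e. the
#: intron as a half-open interval).
Junction = tuple[str, int, int]

EVENT_TYPES = ("cassette_exon", "intron_retention", "alt_5ss", "alt_3ss")


@dataclass
class SplicingEvent:
    """One candidate alternative-splicing event.

    ``inclusion_junctions`` / ``skipping_junctions`` are lists of
    (donor, acceptor) genomic coordinate pairs (intron bounds, donor <
    acceptor).  ``core_interval`` is the cassette exon, the retained
    intron, or the alternative extension, depending on type.
    """

    event_id: str
    event_type: str
    gene_id: str
    inclusion_junctions: list[tuple[int, int]]
    skipping_junctions: list[tuple[int, int]]
    core_interval: GenomicInterval
    annotated: bool = True

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event_type {self.event_type!r}")
        n_inc, n_skip = len(self.inclusion_junctions), len(self.skipping_junctions)
        expected = {
            "cassette_exon": (2, 1),
            "intron_retention": (0, 1),
            "alt_5ss": (1, 1),
            "alt_3ss": (1, 1),
        }[self.event_type]
        if (n_inc, n_skip) != expected:
            raise ValueError(
                f"{self.event_type} event needs {expected} "
                f"(inclusion, skipping) junctions, got ({n_inc}, {n_skip})"
            )
        if set(self.inclusion_junctions) & set(self.skipping_junctions):
            raise ValueError("inclusion and skipping junction sets overlap")
        for d, a in self.inclusion_junctions + self.skipping_junctions:
            if d >= a:
                raise ValueError(f"junction donor {d} must be < acceptor {a}")

    @property
    def chrom(self) -> str:
        return self.core_interval.chrom

    @property
    def strand(self) -> str:
        return self.core_interval.strand
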