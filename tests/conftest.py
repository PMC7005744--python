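"""Shared fixtures: tiny annotations, SAM record builders, and the
engineered AS-NMD transcript geometry."""

from __future__ import annotations

from pathlib import Path

import pysam
import pytest

from sicall.models import GenomicInterval, TranscriptModel

SAM_HEADER = pysam.AlignmentHeader.from_dict(
    {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": "chr1", "LN": 1_000_000}, {"SN": "chr2", "LN": 1_000_000}],
    }
)


def make_read(
    name: str = "r1",
    chrom: str = "chr1",
    pos: int = 0,
    cigar: str = "50M",
    mapq: int = 60,
    flag: int = 0,
) -> pysam.AlignedSegment:
    """One SAM record from 0-based pos and a CIGAR string."""
    length = sum(
        int(n)
        for n, op in __import__("re").findall(r"(\d+)([MIS=X])", cigar)
    )
    seq = "A" * length if length else "*"
    return pysam.AlignedSegment.fromstring(
        f"{name}\t{flag}\t{chrom}\t{pos + 1}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t*",
        SAM_HEADER,
    )


@pytest.fixture
def two_exon_transcript() -> TranscriptModel:
    return TranscriptModel(
        "t1",
        "g1",
        [
            GenomicInterval("chr1", 100, 200, "+"),
            GenomicInterval("chr1", 300, 400, "+"),
        ],
    )


def make_transcript(
    exon_bounds: list[tuple[int, int]],
    strand: str = "+",
    chrom: str = "chr1",
    tid: str = "t1",
    gid: str = "g1",
    cds_start: int | None = None,
) -> TranscriptModel:
    return TranscriptModel(
        tid,
        gid,
        [GenomicInterval(chrom, s, e, strand) for s, e in exon_bounds],
        cds_start=cds_start,
    )


# ---------------------------------------------------------------------------
# Engineered AS-NMD geometry: a six-exon transcript whose frameshifting
# skip of exon 3 creates a stop at the very start of exon 5, 368 nt
# upstream of the last exon-exon junction.

NMD_EXON_LENGTHS = [120, 90, 100, 150, 368, 200]
NMD_CDS_OFFSET = 9  # 5' UTR length within exon 1
NMD_INTRON = 100
NMD_EXPECTED_DISTANCE = 368  # constructed: exon-5 length, PTC at its first base


def build_nmd_gene(tmp_path: Path) -> tuple[TranscriptModel, Path]:
    """Write the engineered gene's genome FASTA and return its model.

    The genome is poly-A (no stop codon anywhere) except a planted TAA
    at the start of exon 5 — in frame only after the frameshifting skip
    of exon 3 — and a terminal TAA near the end of exon 6 in the
    unskipped frame.
    """
    starts = []
    pos = 50
    for ln in NMD_EXON_LENGTHS:
        starts.append(pos)
        pos += ln + NMD_INTRON
    genome_len = pos + 200
    seq = bytearray(b"A" * genome_len)

    # PTC for the skipped isoform: first base of exon 5
    e5 = starts[4]
    seq[e5 : e5 + 3] = b"TAA"
    # terminal stop of the full isoform: full-mRNA codon starting at 1023
    # falls 5 nt before the end of exon 6
    mrna_before_e6 = sum(NMD_EXON_LENGTHS[:5])
    stop_mrna = 1023
    e6_off = stop_mrna - mrna_before_e6
    e6 = starts[5]
    seq[e6 + e6_off : e6 + e6_off + 3] = b"TAA"

    fasta = tmp_path / "nmd_gene.fa"
    with open(fasta, "w") as fh:
        fh.write(">chr1\n")
        raw = seq.decode()
        for i in range(0, len(raw), 70):
            fh.write(raw[i : i + 70] + "\n")

    model = make_transcript(
        [(s, s + ln) for s, ln in zip(starts, NMD_EXON_LENGTHS)],
        cds_start=starts[0] + NMD_CDS_OFFSET,
    )
    return model, fasta
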