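"""AS-NMD logic: exon-skip projection, PTC location, and the 50-nt rule.

Skipping an internal exon whose length is not a multiple of 3 shifts the
downstream reading frame and typically creates a premature termination
codon (PTC).  By the exon-junction-complex rule of thumb, a stop codon
more than ~50 nt upstream of the last exon–exon junction marks the
transcript for nonsense-mediated decay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from pyfaidx import Fasta

from .models import TranscriptModel
from .motif import reverse_complement

STOP_CODONS = {"TAA", "TAG", "TGA"}
DEFAULT_NMD_THRESHOLD = 50  # nt upstream of the last exon-exon junction


def _exon_sequence(genome: Fasta, chrom: str, start: int, end: int, strand: str) -> str:
    seq = str(genome[chrom][start:end]).upper()
    return reverse_complement(seq) if strand == "-" else seq


def spliced_mrna(model: TranscriptModel, genome: Fasta) -> str:
    """Mature mRNA: exon sequences concatenated in transcription order."""
    return "".join(
        _exon_sequence(genome, e.chrom, e.start, e.end, e.strand)
        for e in model.exons
    )


def _mrna_offset(model: TranscriptModel, genomic_pos: int) -> Optional[int]:
    """Map a genomic coordinate into mRNA coordinates; None if intronic."""
    offset = 0
    for e in model.exons:
        if e.start <= genomic_pos < e.end:
            if e.strand == "+":
                return offset + (genomic_pos - e.start)
            return offset + (e.end - 1 - genomic_pos)
        offset += len(e)
    return None


@dataclass
class IsoformProjection:
    parent_transcript_id: str
    skipped_exon_index: Optional[int]
    mrna_sequence: str
    junction_positions: list[int]
    cds_offset: Optional[int]
    frameshift: bool = False
    lost_start_codon: bool = False


def project_transcript(model: TranscriptModel, genome: Fasta) -> IsoformProjection:
    """Projection of the full (no-skip) isoform."""
    return _project(model, genome, None)


def project_skip(
    model: TranscriptModel, exon_index: int, genome: Fasta
) -> IsoformProjection:
    """Project the isoform that skips one internal exon.

    ``exon_index`` is 0-based in transcription order and must be
    internal.  The CDS offset carries over from the annotated start
    codon when its exon survives the skip; otherwise the projection is
    returned with ``cds_offset`` None and ``lost_start_codon`` set.
    """
    if exon_index <= 0 or exon_index >= len(model.exons) - 1:
        raise ValueError(
            f"exon_index must be internal (1..{len(model.exons) - 2}), "
            f"got {exon_index}"
        )
    return _project(model, genome, exon_index)


def _project(
    model: TranscriptModel, genome: Fasta, skip_index: Optional[int]
) -> IsoformProjection:
    exons = [
        e for i, e in enumerate(model.exons) if i != skip_index
    ]
    seqs = [
        _exon_sequence(genome, e.chrom, e.start, e.end, e.strand) for e in exons
    ]
    mrna = "".join(seqs)
    junctions = []
    off = 0
    for s in seqs[:-1]:
        off += len(s)
        junctions.append(off)

    cds_offset = None
    lost_start = False
    frameshift = False
    if model.cds_start is not None:
        kept = TranscriptModel(
            model.transcript_id, model.gene_id, list(exons),
            cds_start=model.cds_start, cds_end=model.cds_end,
        )
        cds_offset = _mrna_offset(kept, model.cds_start)
        if cds_offset is None:
            lost_start = True
        elif skip_index is not None:
            skipped = model.exons[skip_index]
            full_offset = _mrna_offset(model, model.cds_start)
            # frameshift applies when the skipped exon lies in the CDS
            skipped_start_in_mrna = sum(
                len(e) for e in model.exons[:skip_index]
            )
            if full_offset is not None and skipped_start_in_mrna >= full_offset:
                frameshift = len(skipped) % 3 != 0
    return IsoformProjection(
        parent_transcript_id=model.transcript_id,
        skipped_exon_index=skip_index,
        mrna_sequence=mrna,
        junction_positions=junctions,
        cds_offset=cds_offset,
        frameshift=frameshift,
        lost_start_codon=lost_start,
    )


@dataclass
class NMDCall:
    ptc_position: Optional[int]
    distance_to_last_junction: Optional[int]
    nmd_sensitive: bool
    frameshift: bool
    no_stop_found: bool = False


def call_nmd(
    proj: IsoformProjection, rule_threshold: int = DEFAULT_NMD_THRESHOLD
) -> NMDCall:
    """Locate the first in-frame stop and apply the distance rule.

    The PTC position is the mRNA coordinate of the first stop codon
    reached by translating from the start codon.  The distance to the
    last exon–exon junction is positive when the stop lies upstream of
    it; the transcript is NMD-sensitive when that distance exceeds the
    threshold (default 50 nt).  A stop in the last exon gives distance
    <= 0 and is never NMD-sensitive.
    """
    if proj.cds_offset is None:
        raise ValueError("projection has no defined start codon")
    mrna = proj.mrna_sequence
    ptc = None
    for i in range(proj.cds_offset, len(mrna) - 2, 3):
        if mrna[i : i + 3] in STOP_CODONS:
            ptc = i
            break
    if ptc is None:
        return NMDCall(None, None, False, proj.frameshift, no_stop_found=True)
    last_junction = proj.junction_positions[-1] if proj.junction_positions else 0
    distance = last_junction - ptc
    return NMDCall(
        ptc_position=ptc,
        distance_to_last_junction=distance,
        nmd_sensitive=distance > rule_threshold,
        frameshift=proj.frameshift,
    )


def translate(mrna: str, cds_offset: int) -> str:
    """Protein sequence from the start codon to (not including) the stop."""
    table = _codon_table()
    out = []
    for i in range(cds_offset, len(mrna) - 2, 3):
        codon = mrna[i : i + 3]
        if codon in STOP_CODONS:
            break
        out.append(table.get(codon, "X"))
    return "".join(out)


def _codon_table() -> dict[str, str]:
    from Bio.Data.CodonTable import standard_dna_table

    return standard_dna_table.forward_table
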