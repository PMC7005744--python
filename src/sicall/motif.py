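"""Motif-analysis inputs and GA-rich scanning around cassette exons.

Builds the positive (regulator-responsive) and control cassette-exon
sequence sets — exon plus 250 nt flanks on the sense strand — and scans
them with a purine-window rule for GA-rich elements of the kind that
pair with polypyrimidine tracts in double-stranded RNA (e.g. GAAGGAGA).
De-novo motif discovery (MEME) is intentionally external: the FASTA this
module writes is MEME-ready.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from pyfaidx import Fasta

from .differential import ContrastResult, HighConfidenceCall
from .models import SplicingEvent

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DEFAULT_FLANK = 250


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class EventSequence:
    event_id: str
    set_label: str  # positive | control
    sequence: str
    flank: int = DEFAULT_FLANK
    exon_length: int = 0
    truncated: bool = False


@dataclass
class GaRichRule:
    """GA-rich window rule: width 6–9, purines only, >= 2 G and >= 2 A.

    Captures the GAAGGAGA/GAAAAG class of elements while excluding pure
    poly-A or poly-G runs.  Parameters are configurable.
    """

    min_width: int = 6
    max_width: int = 9
    min_g: int = 2
    min_a: int = 2

    def matches(self, window: str) -> bool:
        if not set(window) <= {"A", "G"}:
            return False
        return window.count("G") >= self.min_g and window.count("A") >= self.min_a


@dataclass
class MotifHit:
    event_id: str
    offset: int
    width: int
    matched: str
    region: str  # upstream_flank | exon | downstream_flank


def extract_event_sequence(
    event: SplicingEvent,
    genome: Fasta,
    flank: int = DEFAULT_FLANK,
    set_label: str = "positive",
) -> EventSequence:
    """Exon plus flanks, sense strand of the gene.

    Minus-strand events are reverse-complemented so the returned
    sequence always reads 5'->3' in the direction of transcription;
    the "upstream" flank is then always the transcription-upstream one.
    """
    core = event.core_interval
    chrom_len = len(genome[core.chrom])
    start = max(0, core.start - flank)
    end = min(chrom_len, core.end + flank)
    truncated = start != core.start - flank or end != core.end + flank
    seq = str(genome[core.chrom][start:end]).upper()
    if core.strand == "-":
        seq = reverse_complement(seq)
    return EventSequence(
        event_id=event.event_id,
        set_label=set_label,
        sequence=seq,
        flank=flank,
        exon_length=len(core),
        truncated=truncated,
    )


def build_motif_sets(
    calls: Sequence[HighConfidenceCall],
    all_events: Sequence[SplicingEvent],
    oe_results: Sequence[Sequence[ContrastResult]],
    genome: Fasta,
    flank: int = DEFAULT_FLANK,
    control_max_dsi: float = 0.10,
    seed: int = 0,
) -> tuple[list[EventSequence], list[EventSequence]]:
    """Positive and control cassette-exon sequence sets.

    Positive: called cassette exons.  Control: a size-matched seeded
    random sample of cassette exons with |dSI| < ``control_max_dsi`` in
    every supplied overexpression contrast.  Events whose windows fall
    outside the genome are truncated and flagged.
    """
    by_id = {ev.event_id: ev for ev in all_events if ev.event_type == "cassette_exon"}
    called_ids = [c.event_id for c in calls if c.event_id in by_id]
    positive = [
        extract_event_sequence(by_id[eid], genome, flank, "positive")
        for eid in called_ids
    ]

    oe_maps = [{r.event_id: r for r in rs} for rs in oe_results]
    control_pool = []
    for eid in sorted(by_id):
        if eid in set(called_ids):
            continue
        dsis = [
            m[eid].delta_si
            for m in oe_maps
            if eid in m and m[eid].delta_si is not None
        ]
        if len(dsis) == len(oe_maps) and all(
            abs(d) < control_max_dsi for d in dsis
        ):
            control_pool.append(eid)
    rng = np.random.default_rng(seed)
    n = min(len(positive), len(control_pool))
    chosen = sorted(rng.choice(len(control_pool), size=n, replace=False))
    control = [
        extract_event_sequence(by_id[control_pool[i]], genome, flank, "control")
        for i in chosen
    ]
    return positive, control


def scan_ga_rich(
    event_seq: EventSequence, rule: Optional[GaRichRule] = None
) -> list[MotifHit]:
    """All maximal GA-rich windows, greedy non-overlapping from the left.

    At each position the widest admissible window (max_width down to
    min_width) is taken; scanning resumes past it.  The region label is
    assigned from the hit's start offset relative to the flank
    boundaries.
    """
    rule = rule or GaRichRule()
    seq = event_seq.sequence
    hits = []
    i = 0
    n = len(seq)
    while i + rule.min_width <= n:
        hit_width = 0
        for w in range(min(rule.max_width, n - i), rule.min_width - 1, -1):
            if rule.matches(seq[i : i + w]):
                hit_width = w
                break
        if hit_width:
            if i < event_seq.flank:
                region = "upstream_flank"
            elif i < event_seq.flank + event_seq.exon_length:
                region = "exon"
            else:
                region = "downstream_flank"
            hits.append(
                MotifHit(event_seq.event_id, i, hit_width, seq[i : i + hit_width], region)
            )
            i += hit_width
        else:
            i += 1
    return hits


def motif_fraction(
    sequences: Sequence[EventSequence], rule: Optional[GaRichRule] = None
) -> tuple[int, int, Optional[float]]:
    """(events with >= 1 hit, total events, fraction); fraction None if empty."""
    total = len(sequences)
    if total == 0:
        return 0, 0, None
    with_hit = sum(1 for s in sequences if scan_ga_rich(s, rule))
    return with_hit, total, with_hit / total


def write_fasta(sequences: Sequence[EventSequence], path: Union[str, Path]) -> None:
    """MEME-ready FASTA of event sequences (60-column wrap)."""
    with open(path, "w") as fh:
        for s in sequences:
            fh.write(f">{s.event_id} {s.set_label}\n")
            for i in range(0, len(s.sequence), 60):
                fh.write(s.sequence[i : i + 60] + "\n")


def write_hits(hits: Sequence[MotifHit], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("event_id\toffset\twidth\tmatched\tregion\n")
        for h in hits:
            fh.write(f"{h.event_id}\t{h.offset}\t{h.width}\t{h.matched}\t{h.region}\n")
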