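"""GTF parsing and enumeration of candidate alternative-splicing events.

Candidate events cover the four types analysed throughout the pipeline:
cassette exons, intron retention, and alternative 5'/3' splice sites.
Cassette candidates are enumerated per gene across isoforms, so an exon
present in one isoform and absent from another is a candidate even if no
single transcript witnesses both forms.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence, Union

import gffutils

from .models import GenomicInterval, SplicingEvent, TranscriptModel

logger = logging.getLogger(__name__)


class GtfParseError(ValueError):
    pass


def _validate_gtf_lines(path: Path) -> None:
    """Cheap structural validation so errors can name the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GtfParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise GtfParseError(
                    f"{path}:{lineno}: invalid coordinate range {start}-{end}"
                )


def parse_gtf(path: Union[str, Path]) -> list[TranscriptModel]:
    """Parse a GTF file into transcript models.

    GTF 1-based inclusive coordinates are converted to the internal
    0-based half-open convention.  Transcripts without exon records are
    dropped with a warning; transcripts mixing strands are rejected with
    a warning.  Both Ensembl and GENCODE attribute dialects are accepted
    (gffutils handles the quoting differences).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_gtf_lines(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    exons: dict[str, list] = defaultdict(list)
    gene_of: dict[str, str] = {}
    cds: dict[str, list] = defaultdict(list)
    start_codons: dict[str, list] = defaultdict(list)
    stop_codons: dict[str, list] = defaultdict(list)
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS", "start_codon", "stop_codon"):
            continue
        tids = feat.attributes.get("transcript_id")
        gids = feat.attributes.get("gene_id")
        if not tids or not gids:
            raise GtfParseError(
                f"{path}: {feat.featuretype} record at {feat.seqid}:{feat.start} "
                "lacks gene_id/transcript_id attributes"
            )
        tid, gid = tids[0], gids[0]
        gene_of[tid] = gid
        rec = (feat.seqid, feat.start - 1, feat.end, feat.strand)
        {"exon": exons, "CDS": cds, "start_codon": start_codons,
         "stop_codon": stop_codons}[feat.featuretype][tid].append(rec)

    models: list[TranscriptModel] = []
    for tid, gid in gene_of.items():
        recs = exons.get(tid)
        if not recs:
            logger.warning("transcript %s has no exon records; dropped", tid)
            continue
        strands = {r[3] for r in recs}
        if len(strands) != 1:
            logger.warning("transcript %s mixes strands; rejected", tid)
            continue
        ivs = [GenomicInterval(c, s, e, st) for c, s, e, st in recs]
        strand = recs[0][3]
        cds_start = cds_end = None
        if tid in start_codons:
            c, s, e, st = start_codons[tid][0]
            cds_start = s if strand == "+" else e - 1
        elif tid in cds:
            segs = sorted(cds[tid], key=lambda r: r[1])
            cds_start = segs[0][1] if strand == "+" else segs[-1][2] - 1
        if tid in stop_codons:
            c, s, e, st = stop_codons[tid][0]
            cds_end = s if strand == "+" else e - 1
        try:
            models.append(
                TranscriptModel(tid, gid, ivs, cds_start=cds_start, cds_end=cds_end)
            )
        except ValueError as exc:
            logger.warning("transcript %s rejected: %s", tid, exc)
    return models


def _gene_groups(
    models: Iterable[TranscriptModel],
) -> dict[str, list[TranscriptModel]]:
    groups: dict[str, list[TranscriptModel]] = defaultdict(list)
    for m in models:
        groups[m.gene_id].append(m)
    return groups


def enumerate_events(models: Sequence[TranscriptModel]) -> list[SplicingEvent]:
    """Enumerate candidate events from transcript models, per gene.

    * every internal exon flanked by two annotated introns yields one
      cassette-exon candidate; its skipping junction is the direct
      flank-to-flank junction, flagged ``annotated`` when some isoform
      witnesses it;
    * every annotated intron yields one intron-retention candidate;
    * junction pairs sharing one splice site and differing at the other
      yield alternative 5'/3' splice-site candidates (strand-aware).

    Output order and event ids are deterministic functions of the
    coordinates.
    """
    events: dict[str, SplicingEvent] = {}
    groups = _gene_groups(models)
    for gene_id in sorted(groups):
        group = groups[gene_id]
        strand = group[0].strand
        chrom = group[0].chrom
        junctions: set[tuple[int, int]] = set()
        for m in group:
            for iv in m.introns():
                junctions.add((iv.start, iv.end))

        # cassette exons: internal exon + its two flanking introns
        for m in group:
            ex = m.exons_genomic
            for i in range(1, len(ex) - 1):
                up = (ex[i - 1].end, ex[i].start)
                down = (ex[i].end, ex[i + 1].start)
                skip = (up[0], down[1])
                eid = (
                    f"CE:{chrom}:{strand}:{up[0]}-{ex[i].start}"
                    f":{ex[i].end}-{down[1]}"
                )
                if eid not in events:
                    events[eid] = SplicingEvent(
                        event_id=eid,
                        event_type="cassette_exon",
                        gene_id=gene_id,
                        inclusion_junctions=[up, down],
                        skipping_junctions=[skip],
                        core_interval=GenomicInterval(
                            chrom, ex[i].start, ex[i].end, strand
                        ),
                        annotated=skip in junctions,
                    )
                elif skip in junctions:
                    events[eid].annotated = True

        # intron retention: one candidate per annotated intron
        for d, a in sorted(junctions):
            eid = f"IR:{chrom}:{strand}:{d}-{a}"
            events.setdefault(
                eid,
                SplicingEvent(
                    event_id=eid,
                    event_type="intron_retention",
                    gene_id=gene_id,
                    inclusion_junctions=[],
                    skipping_junctions=[(d, a)],
                    core_interval=GenomicInterval(chrom, d, a, strand),
                    annotated=True,
                ),
            )

        # alternative splice sites: junction pairs sharing one end
        by_start: dict[int, list[int]] = defaultdict(list)
        by_end: dict[int, list[int]] = defaultdict(list)
        for d, a in junctions:
            by_start[d].append(a)
            by_end[a].append(d)
        # shared genomic end, differing start
        for a, donors in sorted(by_end.items()):
            donors = sorted(donors)
            for d1, d2 in zip(donors, donors[1:]):
                # d1 < d2: the longer-exon (shorter-intron) junction is (d2, a)
                # on +, the varying site is the donor (5'ss); on -, acceptor.
                etype = "alt_5ss" if strand == "+" else "alt_3ss"
                eid = f"{'A5' if etype == 'alt_5ss' else 'A3'}:{chrom}:{strand}:{d1}|{d2}-{a}"
                events.setdefault(
                    eid,
                    SplicingEvent(
                        event_id=eid,
                        event_type=etype,
                        gene_id=gene_id,
                        inclusion_junctions=[(d2, a)],
                        skipping_junctions=[(d1, a)],
                        core_interval=GenomicInterval(chrom, d1, d2, strand),
                        annotated=True,
                    ),
                )
        # shared genomic start, differing end
        for d, accs in sorted(by_start.items()):
            accs = sorted(accs)
            for a1, a2 in zip(accs, accs[1:]):
                etype = "alt_3ss" if strand == "+" else "alt_5ss"
                eid = f"{'A3' if etype == 'alt_3ss' else 'A5'}:{chrom}:{strand}:{d}-{a1}|{a2}"
                events.setdefault(
                    eid,
                    SplicingEvent(
                        event_id=eid,
                        event_type=etype,
                        gene_id=gene_id,
                        inclusion_junctions=[(d, a1)],
                        skipping_junctions=[(d, a2)],
                        core_interval=GenomicInterval(chrom, a1, a2, strand),
                        annotated=True,
                    ),
                )
    return [events[k] for k in sorted(events)]


EVENTS_COLUMNS = [
    "event_id",
    "event_type",
    "gene_id",
    "chrom",
    "strand",
    "core_start",
    "core_end",
    "inclusion_junctions",
    "skipping_junctions",
    "annotated",
]


def _fmt_junctions(juncs: list[tuple[int, int]]) -> str:
    return ";".join(f"{d}-{a}" for d, a in juncs) or "."


def _parse_junctions(text: str) -> list[tuple[int, int]]:
    if text == ".":
        return []
    out = []
    for part in text.split(";"):
        d, a = part.split("-")
        out.append((int(d), int(a)))
    return out


def write_events(events: Sequence[SplicingEvent], path: Union[str, Path]) -> None:
    """Write events to the tab-separated interchange format."""
    with open(path, "w") as fh:
        fh.write("\t".join(EVENTS_COLUMNS) + "\n")
        for ev in events:
            fh.write(
                "\t".join(
                    [
                        ev.event_id,
                        ev.event_type,
                        ev.gene_id,
                        ev.chrom,
                        ev.strand,
                        str(ev.core_interval.start),
                        str(ev.core_interval.end),
                        _fmt_junctions(ev.inclusion_junctions),
                        _fmt_junctions(ev.skipping_junctions),
                        "1" if ev.annotated else "0",
                    ]
                )
                + "\n"
            )


def read_events(path: Union[str, Path]) -> list[SplicingEvent]:
    """Read events written by :func:`write_events`."""
    events = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != EVENTS_COLUMNS:
            raise ValueError(f"{path}: unexpected events header {header}")
        for lineno, line in enumerate(fh, start=2):
            f = line.rstrip("\n").split("\t")
            if len(f) != len(EVENTS_COLUMNS):
                raise ValueError(f"{path}:{lineno}: bad column count")
            events.append(
                SplicingEvent(
                    event_id=f[0],
                    event_type=f[1],
                    gene_id=f[2],
                    inclusion_junctions=_parse_junctions(f[7]),
                    skipping_junctions=_parse_junctions(f[8]),
                    core_interval=GenomicInterval(f[3], int(f[5]), int(f[6]), f[4]),
                    annotated=f[9] == "1",
                )
            )
    return events
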