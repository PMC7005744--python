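"""Junction extraction from spliced alignments and per-sample counting.

Mapped reads are classified into three groups around annotated splice
sites: (1) exon–exon junction reads (CIGAR N gaps), (2) reads bridging
an exon–intron boundary, and (3) reads fully inside an intron.  Group 1
and 2 counts feed the splicing-index calculation; group 3 feeds
intron-retention coverage and depth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pysam
from intervaltree import IntervalTree

from .models import TranscriptModel

logger = logging.getLogger(__name__)

TABLE_FORMAT_VERSION = "1"


class ReadClass(Enum):
    EXON_EXON_JUNCTION = "exon_exon_junction"
    EXON_INTRON_BRIDGING = "exon_intron_bridging"
    FULLY_INTRONIC = "fully_intronic"
    UNCLASSIFIED = "unclassified"


@dataclass
class ReadFilters:
    """QC thresholds applied before counting.

    The originating study states only that mapped reads were "filtered";
    these are explicit, configurable junction-QC defaults.
    """

    min_mapq: int = 20
    min_overhang: int = 6
    require_primary: bool = True
    exclude_duplicates: bool = True


class SpliceSiteIndex:
    """Annotated junctions, exon/intron intervals for read classification."""

    def __init__(self, models: Iterable[TranscriptModel]):
        self.junctions: set[tuple[str, int, int]] = set()
        self.junction_strand: dict[tuple[str, int, int], str] = {}
        self._introns: dict[str, IntervalTree] = {}
        self._exons: dict[str, IntervalTree] = {}
        for m in models:
            for iv in m.introns():
                key = (iv.chrom, iv.start, iv.end)
                self.junctions.add(key)
                self.junction_strand[key] = iv.strand
                self._introns.setdefault(iv.chrom, IntervalTree()).addi(
                    iv.start, iv.end, iv.strand
                )
            for e in m.exons_genomic:
                self._exons.setdefault(e.chrom, IntervalTree()).addi(
                    e.start, e.end, e.strand
                )

    def intron_intervals(self, chrom: str) -> IntervalTree:
        return self._introns.get(chrom, IntervalTree())

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._introns or chrom in self._exons

    def enclosing_intron(self, chrom: str, start: int, end: int):
        for iv in self.intron_intervals(chrom).overlap(start, end):
            if iv.begin <= start and end <= iv.end:
                return iv
        return None

    def boundaries_in(self, chrom: str, start: int, end: int) -> list[int]:
        """Exon–intron boundary coordinates within [start, end]."""
        out = set()
        for iv in self.intron_intervals(chrom).overlap(start - 1, end + 1):
            for b in (iv.begin, iv.end):
                if start <= b <= end:
                    out.add(b)
        return sorted(out)

    def overlaps_exon(self, chrom: str, start: int, end: int) -> bool:
        return bool(self._exons.get(chrom, IntervalTree()).overlap(start, end))


@dataclass
class JunctionCountTable:
    """Per-sample junction / bridging / intron-depth summaries.

    ``junction_counts`` maps (chrom, donor, acceptor, strand) to the
    number of distinct supporting fragments ('.' strand = undetermined).
    ``bridging_counts`` maps (chrom, boundary coordinate) to fragment
    counts.  ``intron_depth`` maps (chrom, start, end) to
    (covered_fraction, mean_depth).
    """

    sample_id: str
    junction_counts: dict[tuple[str, int, int, str], int] = field(default_factory=dict)
    bridging_counts: dict[tuple[str, int], int] = field(default_factory=dict)
    intron_depth: dict[tuple[str, int, int], tuple[float, float]] = field(
        default_factory=dict
    )
    qc: dict[str, int] = field(default_factory=dict)
    _coord_cache: Optional[dict[tuple[str, int, int], int]] = field(
        default=None, repr=False, compare=False
    )

    def junction_count(self, chrom: str, donor: int, acceptor: int) -> int:
        """Count for a junction, summing over strand annotations."""
        if self._coord_cache is None:
            cache: dict[tuple[str, int, int], int] = {}
            for (c, d, a, _s), n in self.junction_counts.items():
                key = (c, d, a)
                cache[key] = cache.get(key, 0) + n
            self._coord_cache = cache
        return self._coord_cache.get((chrom, donor, acceptor), 0)

    def add_junction(
        self, chrom: str, donor: int, acceptor: int, strand: str = ".", n: int = 1
    ) -> None:
        key = (chrom, donor, acceptor, strand)
        self.junction_counts[key] = self.junction_counts.get(key, 0) + n
        self._coord_cache = None

    def merge(self, other: "JunctionCountTable") -> "JunctionCountTable":
        out = JunctionCountTable(sample_id=self.sample_id)
        for src in (self, other):
            for k, v in src.junction_counts.items():
                out.junction_counts[k] = out.junction_counts.get(k, 0) + v
            for k, v in src.bridging_counts.items():
                out.bridging_counts[k] = out.bridging_counts.get(k, 0) + v
            out.intron_depth.update(src.intron_depth)
        return out


def extract_junctions(alignment: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Junctions implied by the N operations of one alignment.

    Returns (donor, acceptor) pairs in 0-based coordinates: donor is the
    reference coordinate where the gap begins, acceptor where it ends.
    M/D/N/=/X consume reference; I/S/H/P do not.
    """
    if alignment.is_unmapped or alignment.cigartuples is None:
        return []
    pos = alignment.reference_start
    out = []
    for op, length in alignment.cigartuples:
        if op == 3:  # N
            out.append((pos, pos + length))
            pos += length
        elif op in (0, 2, 7, 8):  # M, D, =, X
            pos += length
    return out


def _junction_overhangs(alignment: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Reference-consuming lengths flanking each N gap."""
    out = []
    run = 0
    gaps = []
    for op, length in alignment.cigartuples or []:
        if op == 3:
            gaps.append(run)
            run = 0
        elif op in (0, 2, 7, 8):
            run += length
    gaps.append(run)
    for i in range(len(gaps) - 1):
        out.append((gaps[i], gaps[i + 1]))
    return out


def classify_read(
    alignment: pysam.AlignedSegment,
    index: SpliceSiteIndex,
    min_overhang: int = 6,
) -> ReadClass:
    """Assign one read to the junction / bridging / intronic partition.

    Precedence: exon_exon_junction > exon_intron_bridging >
    fully_intronic > unclassified.  A spliced read counts as a junction
    read when at least one of its gaps is an annotated junction or a
    plausible novel one (donor < acceptor, which CIGAR semantics
    guarantee).
    """
    chrom = alignment.reference_name
    juncs = extract_junctions(alignment)
    if juncs:
        return ReadClass.EXON_EXON_JUNCTION
    if chrom is None or not index.has_chrom(chrom):
        return ReadClass.UNCLASSIFIED
    start, end = alignment.reference_start, alignment.reference_end
    if index.boundaries_in(chrom, start + min_overhang, end - min_overhang):
        return ReadClass.EXON_INTRON_BRIDGING
    if index.enclosing_intron(chrom, start, end) is not None:
        return ReadClass.FULLY_INTRONIC
    return ReadClass.UNCLASSIFIED


def _passes_filters(aln: pysam.AlignedSegment, filters: ReadFilters) -> bool:
    if aln.is_unmapped:
        return False
    if filters.require_primary and (aln.is_secondary or aln.is_supplementary):
        return False
    if filters.exclude_duplicates and aln.is_duplicate:
        return False
    if aln.mapping_quality < filters.min_mapq:
        return False
    return True


def count_sample(
    alignments: Union[str, Path, Iterable[pysam.AlignedSegment]],
    index: SpliceSiteIndex,
    filters: Optional[ReadFilters] = None,
    sample_id: str = "sample",
) -> JunctionCountTable:
    """Aggregate one SAM stream into a junction count table.

    Counting is fragment-level: a junction supported by both mates of a
    pair counts once.  Junction anchors shorter than the overhang
    threshold are ignored for that junction (the read may still support
    its other junctions).  Intron depth summaries come from fully
    intronic reads only.
    """
    filters = filters or ReadFilters()
    table = JunctionCountTable(sample_id=sample_id)
    qc = {
        "reads_seen": 0,
        "reads_filtered": 0,
        "reads_passed": 0,
        "exon_exon_junction": 0,
        "exon_intron_bridging": 0,
        "fully_intronic": 0,
        "unclassified": 0,
        "invalid_cigar": 0,
    }
    # fragment-level dedup: (qname, junction) and (qname, boundary)
    seen_junc: set[tuple[str, str, int, int]] = set()
    seen_bridge: set[tuple[str, str, int]] = set()
    intron_cov: dict[tuple[str, int, int], np.ndarray] = {}

    owns_handle = isinstance(alignments, (str, Path))
    if owns_handle:
        handle = pysam.AlignmentFile(str(alignments), "r", check_sq=False)
        stream: Iterable[pysam.AlignedSegment] = handle
    else:
        stream = alignments

    try:
        for aln in stream:
            qc["reads_seen"] += 1
            if not _passes_filters(aln, filters):
                qc["reads_filtered"] += 1
                continue
            if aln.cigartuples is None:
                qc["invalid_cigar"] += 1
                qc["reads_filtered"] += 1
                continue
            qc["reads_passed"] += 1
            chrom = aln.reference_name
            cls = classify_read(aln, index, min_overhang=filters.min_overhang)
            qc[cls.value] += 1
            if cls is ReadClass.EXON_EXON_JUNCTION:
                juncs = extract_junctions(aln)
                overhangs = _junction_overhangs(aln)
                for (d, a), (left, right) in zip(juncs, overhangs):
                    if left < filters.min_overhang or right < filters.min_overhang:
                        continue
                    fkey = (aln.query_name, chrom, d, a)
                    if fkey in seen_junc:
                        continue
                    seen_junc.add(fkey)
                    strand = index.junction_strand.get((chrom, d, a), ".")
                    table.add_junction(chrom, d, a, strand)
            elif cls is ReadClass.EXON_INTRON_BRIDGING:
                start, end = aln.reference_start, aln.reference_end
                for b in index.boundaries_in(
                    chrom, start + filters.min_overhang, end - filters.min_overhang
                ):
                    fkey = (aln.query_name, chrom, b)
                    if fkey in seen_bridge:
                        continue
                    seen_bridge.add(fkey)
                    key = (chrom, b)
                    table.bridging_counts[key] = table.bridging_counts.get(key, 0) + 1
            elif cls is ReadClass.FULLY_INTRONIC:
                start, end = aln.reference_start, aln.reference_end
                iv = index.enclosing_intron(chrom, start, end)
                key = (chrom, iv.begin, iv.end)
                arr = intron_cov.get(key)
                if arr is None:
                    arr = np.zeros(iv.end - iv.begin, dtype=np.int32)
                    intron_cov[key] = arr
                arr[start - iv.begin : end - iv.begin] += 1
    finally:
        if owns_handle:
            handle.close()

    for (chrom, s, e), arr in intron_cov.items():
        covered = float(np.mean(arr > 0))
        table.intron_depth[(chrom, s, e)] = (covered, float(np.mean(arr)))
    table.qc = qc
    if qc["reads_seen"] == 0:
        logger.warning("sample %s: empty alignment stream", sample_id)
    return table


def read_sj_table(
    path: Union[str, Path],
    index: Optional[SpliceSiteIndex] = None,
    sample_id: Optional[str] = None,
    include_multimappers: bool = False,
) -> JunctionCountTable:
    """Read a STAR SJ.out.tab splice-junction table.

    Columns: chrom, intron start (1-based), intron end (1-based
    inclusive), strand code (0 undefined / 1 '+' / 2 '-'), motif code,
    annotated flag, unique reads, multimapping reads, max overhang.
    Junctions with strand code 0 take their strand from the annotation
    when an index is supplied, otherwise they are dropped.
    """
    path = Path(path)
    table = JunctionCountTable(sample_id=sample_id or path.stem)
    strand_map = {"0": ".", "1": "+", "2": "-"}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 columns, got {len(f)}"
                )
            chrom = f[0]
            donor = int(f[1]) - 1  # first intron base, 1-based -> 0-based
            acceptor = int(f[2])  # last intron base, 1-based -> exclusive end
            strand = strand_map.get(f[3])
            if strand is None:
                raise ValueError(f"{path}:{lineno}: bad strand code {f[3]!r}")
            count = int(f[6])
            if include_multimappers:
                count += int(f[7])
            if strand == ".":
                if index is not None:
                    strand = index.junction_strand.get((chrom, donor, acceptor), ".")
                if strand == ".":
                    continue  # undefined strand, unresolvable: dropped
            if count > 0:
                table.add_junction(chrom, donor, acceptor, strand, n=count)
    return table


# ---------------------------------------------------------------------------
# TSV round-trip for count tables


def write_count_table(table: JunctionCountTable, path: Union[str, Path]) -> None:
    """Write a count table as a versioned three-section TSV."""
    with open(path, "w") as fh:
        fh.write(
            f"#sicall_counts\tversion={TABLE_FORMAT_VERSION}"
            f"\tsample={table.sample_id}\n"
        )
        for (c, d, a, s), n in sorted(table.junction_counts.items()):
            fh.write(f"J\t{c}\t{d}\t{a}\t{s}\t{n}\n")
        for (c, b), n in sorted(table.bridging_counts.items()):
            fh.write(f"B\t{c}\t{b}\t{n}\n")
        for (c, s, e), (cov, depth) in sorted(table.intron_depth.items()):
            fh.write(f"I\t{c}\t{s}\t{e}\t{cov:.6g}\t{depth:.6g}\n")
    qc_path = Path(str(path) + ".qc.json")
    with open(qc_path, "w") as fh:
        json.dump(table.qc, fh, indent=0, sort_keys=True)


def read_count_table(path: Union[str, Path]) -> JunctionCountTable:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#sicall_counts"):
            raise ValueError(f"{path}: not a sicall count table")
        sample = dict(
            part.split("=", 1) for part in header.split("\t")[1:]
        ).get("sample", path.stem)
        table = JunctionCountTable(sample_id=sample)
        for lineno, line in enumerate(fh, start=2):
            f = line.rstrip("\n").split("\t")
            if f[0] == "J":
                table.add_junction(f[1], int(f[2]), int(f[3]), f[4], int(f[5]))
            elif f[0] == "B":
                table.bridging_counts[(f[1], int(f[2]))] = int(f[3])
            elif f[0] == "I":
                table.intron_depth[(f[1], int(f[2]), int(f[3]))] = (
                    float(f[4]),
                    float(f[5]),
                )
            else:
                raise ValueError(f"{path}:{lineno}: unknown record type {f[0]!r}")
    qc_path = Path(str(path) + ".qc.json")
    if qc_path.exists():
        table.qc = json.loads(qc_path.read_text())
    return table
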