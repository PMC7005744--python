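"""Splicing-index quantification per event and sample.

The splicing index (SI) of an event is the ratio of inclusion junction
reads to the sum of inclusion and skipping junction reads — a per-sample
percent-spliced-in measured from junction evidence.  How the raw counts
map onto "inclusion" and "skipping" is adjusted per event type:

* cassette exon — inclusion is the (rounded) mean of the two flanking
  inclusion-junction counts, skipping is the exon-skipping junction;
* alternative 5'/3' splice site — inclusion is the longer-exon
  (shorter-intron) junction, skipping the alternative junction;
* intron retention — inclusion is the mean of the bridging counts at
  the two intron boundaries, skipping the spliced junction; intronic
  coverage/depth ride along as QC fields.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

from .junctions import JunctionCountTable
from .models import SplicingEvent

#: combiners for the two inclusion-side counts of cassette / IR events
_COMBINERS: dict[str, Callable[[int, int], float]] = {
    "mean": lambda a, b: (a + b) / 2,
    "sum": lambda a, b: float(a + b),
    "min": lambda a, b: float(min(a, b)),
}


def _round_half_even(x: float) -> int:
    return int(round(x))  # Python 3 banker's rounding


@dataclass
class EventQuantification:
    event_id: str
    sample_id: str
    inclusion_reads: int
    skipping_reads: int
    ir_covered_fraction: Optional[float] = None
    ir_mean_depth: Optional[float] = None

    @property
    def total_junction_reads(self) -> int:
        return self.inclusion_reads + self.skipping_reads

    @property
    def si(self) -> Optional[float]:
        """Inclusion reads over total junction reads; None when total is 0."""
        total = self.total_junction_reads
        if total == 0:
            return None
        return self.inclusion_reads / total


def quantify_event(
    event: SplicingEvent,
    table: JunctionCountTable,
    combiner: str = "mean",
) -> EventQuantification:
    """Quantify one event against one sample's count table."""
    combine = _COMBINERS[combiner]
    chrom = event.chrom
    if event.event_type == "cassette_exon":
        (d1, a1), (d2, a2) = event.inclusion_junctions
        inc = _round_half_even(
            combine(
                table.junction_count(chrom, d1, a1),
                table.junction_count(chrom, d2, a2),
            )
        )
        ds, as_ = event.skipping_junctions[0]
        skip = table.junction_count(chrom, ds, as_)
        return EventQuantification(event.event_id, table.sample_id, inc, skip)
    if event.event_type in ("alt_5ss", "alt_3ss"):
        d, a = event.inclusion_junctions[0]
        inc = table.junction_count(chrom, d, a)
        d, a = event.skipping_junctions[0]
        skip = table.junction_count(chrom, d, a)
        return EventQuantification(event.event_id, table.sample_id, inc, skip)
    if event.event_type == "intron_retention":
        d, a = event.skipping_junctions[0]
        skip = table.junction_count(chrom, d, a)
        left = table.bridging_counts.get((chrom, d), 0)
        right = table.bridging_counts.get((chrom, a), 0)
        inc = _round_half_even(combine(left, right))
        cov, depth = table.intron_depth.get((chrom, d, a), (0.0, 0.0))
        return EventQuantification(
            event.event_id,
            table.sample_id,
            inc,
            skip,
            ir_covered_fraction=cov,
            ir_mean_depth=depth,
        )
    raise ValueError(f"unknown event type {event.event_type!r}")


def quantify_all(
    events: Sequence[SplicingEvent],
    table: JunctionCountTable,
    combiner: str = "mean",
) -> dict[str, EventQuantification]:
    return {ev.event_id: quantify_event(ev, table, combiner) for ev in events}


def psi_from_band_intensities(
    inclusion_intensity: float, skipping_intensity: float
) -> float:
    """Percent-spliced-in from RT-PCR band intensities.

    Mirrors the gel-based PSI: inclusion band over the sum of inclusion
    and skipping bands.
    """
    if inclusion_intensity < 0 or skipping_intensity < 0:
        raise ValueError("band intensities must be non-negative")
    total = inclusion_intensity + skipping_intensity
    if total == 0:
        raise ValueError("both band intensities are zero; PSI undefined")
    return inclusion_intensity / total


QUANT_COLUMNS = [
    "event_id",
    "sample_id",
    "inclusion_reads",
    "skipping_reads",
    "si",
    "total_junction_reads",
    "ir_covered_fraction",
    "ir_mean_depth",
]


def write_quantifications(
    quants: Sequence[EventQuantification], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(QUANT_COLUMNS) + "\n")
        for q in quants:
            si = "NA" if q.si is None else f"{q.si:.6g}"
            cov = "NA" if q.ir_covered_fraction is None else f"{q.ir_covered_fraction:.6g}"
            dep = "NA" if q.ir_mean_depth is None else f"{q.ir_mean_depth:.6g}"
            fh.write(
                f"{q.event_id}\t{q.sample_id}\t{q.inclusion_reads}"
                f"\t{q.skipping_reads}\t{si}\t{q.total_junction_reads}"
                f"\t{cov}\t{dep}\n"
            )


def read_quantifications(path: Union[str, Path]) -> list[EventQuantification]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != QUANT_COLUMNS:
            raise ValueError(f"{path}: unexpected quantification header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                EventQuantification(
                    event_id=f[0],
                    sample_id=f[1],
                    inclusion_reads=int(f[2]),
                    skipping_reads=int(f[3]),
                    ir_covered_fraction=None if f[6] == "NA" else float(f[6]),
                    ir_mean_depth=None if f[7] == "NA" else float(f[7]),
                )
            )
    return out
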