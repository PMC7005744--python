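"""GTF parsing and splicing-event enumeration."""

from __future__ import annotations

import pytest

from sicall.annotation import (
    GtfParseError,
    enumerate_events,
    parse_gtf,
    read_events,
    write_events,
)
from sicall.models import GenomicInterval, SplicingEvent, TranscriptModel

from conftest import make_transcript


def gtf_line(chrom, feat, start, end, strand, gid, tid):
    return (
        f"{chrom}\tsrc\t{feat}\t{start}\t{end}\t.\t{strand}\t.\t"
        f'gene_id "{gid}"; transcript_id "{tid}";\n'
    )


class TestParseGtf:
    def test_one_based_inclusive_converted_to_half_open(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(gtf_line("chr1", "exon", 101, 200, "+", "g1", "t1"))
        (model,) = parse_gtf(p)
        assert model.exons[0] == GenomicInterval("chr1", 100, 200, "+")

    def test_consecutive_exons_imply_intron(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            gtf_line("chr1", "exon", 101, 200, "+", "g1", "t1")
            + gtf_line("chr1", "exon", 301, 400, "+", "g1", "t1")
        )
        (model,) = parse_gtf(p)
        assert model.introns() == [GenomicInterval("chr1", 200, 300, "+")]

    def test_mixed_strand_transcript_rejected(self, tmp_path, caplog):
        p = tmp_path / "a.gtf"
        p.write_text(
            gtf_line("chr1", "exon", 101, 200, "+", "g1", "t1")
            + gtf_line("chr1", "exon", 301, 400, "-", "g1", "t1")
        )
        assert parse_gtf(p) == []
        assert "mixes strands" in caplog.text

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            gtf_line("chr1", "exon", 101, 200, "+", "g1", "t1") + "chr1\tbroken\n"
        )
        with pytest.raises(GtfParseError, match=":2:"):
            parse_gtf(p)

    def test_minus_strand_exons_in_transcription_order(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            gtf_line("chr1", "exon", 101, 200, "-", "g1", "t1")
            + gtf_line("chr1", "exon", 301, 400, "-", "g1", "t1")
        )
        (model,) = parse_gtf(p)
        assert [e.start for e in model.exons] == [300, 100]

    def test_start_codon_sets_cds_anchor(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            gtf_line("chr1", "exon", 101, 200, "+", "g1", "t1")
            + gtf_line("chr1", "start_codon", 111, 113, "+", "g1", "t1")
        )
        (model,) = parse_gtf(p)
        assert model.cds_start == 110


class TestEnumerateEvents:
    def test_three_exon_transcript_yields_forced_events(self):
        t = make_transcript([(100, 200), (300, 400), (500, 600)])
        events = enumerate_events([t])
        by_type = {}
        for e in events:
            by_type.setdefault(e.event_type, []).append(e)
        assert len(by_type["cassette_exon"]) == 1
        assert len(by_type["intron_retention"]) == 2
        assert "alt_5ss" not in by_type and "alt_3ss" not in by_type
        (ce,) = by_type["cassette_exon"]
        assert ce.inclusion_junctions == [(200, 300), (400, 500)]
        assert ce.skipping_junctions == [(200, 500)]
        assert ce.annotated is False  # no isoform skips exon B

    @pytest.mark.parametrize("n_exons", [3, 5, 8])
    def test_candidate_counts_scale_with_exons(self, n_exons):
        bounds = [(i * 1000, i * 1000 + 100) for i in range(n_exons)]
        events = enumerate_events([make_transcript(bounds)])
        n_ce = sum(e.event_type == "cassette_exon" for e in events)
        n_ir = sum(e.event_type == "intron_retention" for e in events)
        assert n_ce == n_exons - 2
        assert n_ir == n_exons - 1

    def test_single_exon_transcript_contributes_nothing(self):
        assert enumerate_events([make_transcript([(100, 200)])]) == []

    def test_shared_acceptor_differing_donors_is_alt5ss_on_plus(self):
        t1 = make_transcript([(100, 200), (500, 600)], tid="t1")
        t2 = make_transcript([(100, 300), (500, 600)], tid="t2")
        events = enumerate_events([t1, t2])
        alt = [e for e in events if e.event_type == "alt_5ss"]
        assert len(alt) == 1
        # the longer-exon junction (300, 500) defines inclusion
        assert alt[0].inclusion_junctions == [(300, 500)]
        assert alt[0].skipping_junctions == [(200, 500)]

    def test_shared_acceptor_differing_donors_is_alt3ss_on_minus(self):
        t1 = make_transcript([(100, 200), (500, 600)], strand="-", tid="t1")
        t2 = make_transcript([(100, 300), (500, 600)], strand="-", tid="t2")
        events = enumerate_events([t1, t2])
        assert sum(e.event_type == "alt_3ss" for e in events) == 1

    def test_skipping_isoform_marks_cassette_annotated(self):
        t1 = make_transcript([(100, 200), (300, 400), (500, 600)], tid="t1")
        t2 = make_transcript([(100, 200), (500, 600)], tid="t2")
        (ce,) = [
            e
            for e in enumerate_events([t1, t2])
            if e.event_type == "cassette_exon"
        ]
        assert ce.annotated is True

    def test_enumeration_is_deterministic(self):
        ts = [
            make_transcript([(100, 200), (300, 400), (500, 600)], tid="t1"),
            make_transcript([(100, 200), (500, 600)], tid="t2"),
            make_transcript([(90, 200), (300, 400)], tid="t3", gid="g2"),
        ]
        assert enumerate_events(ts) == enumerate_events(list(ts))


class TestEventsRoundTrip:
    def test_write_read_write_is_byte_identical(self, tmp_path):
        ts = [
            make_transcript([(100, 200), (300, 400), (500, 600)], tid="t1"),
            make_transcript([(100, 200), (500, 600)], tid="t2"),
        ]
        events = enumerate_events(ts)
        p1, p2 = tmp_path / "e1.tsv", tmp_path / "e2.tsv"
        write_events(events, p1)
        back = read_events(p1)
        assert back == events
        write_events(back, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_event_invariants_enforced(self):
        with pytest.raises(ValueError, match="junctions"):
            SplicingEvent(
                "x",
                "cassette_exon",
                "g",
                inclusion_junctions=[(1, 2)],
                skipping_junctions=[(0, 3)],
                core_interval=GenomicInterval("chr1", 1, 2, "+"),
            )
        with pytest.raises(ValueError, match="overlap"):
            SplicingEvent(
                "x",
                "alt_5ss",
                "g",
                inclusion_junctions=[(1, 5)],
                skipping_junctions=[(1, 5)],
                core_interval=GenomicInterval("chr1", 1, 5, "+"),
            )
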