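"""CIGAR junction extraction, read classification, and sample counting."""

from __future__ import annotations

import re

import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sicall.junctions import (
    JunctionCountTable,
    ReadClass,
    ReadFilters,
    SpliceSiteIndex,
    classify_read,
    count_sample,
    extract_junctions,
    read_count_table,
    read_sj_table,
    write_count_table,
)

from conftest import make_read, make_transcript


class TestExtractJunctions:
    @pytest.mark.parametrize(
        "pos,cigar,expected",
        [
            (100, "20M100N30M", [(120, 220)]),
            (0, "50M", []),
            (0, "10M5I10M200N20M", [(20, 220)]),  # I consumes no reference
            (0, "5S10M100N10M3S", [(10, 110)]),  # S consumes no reference
            (0, "10M2D5M50N5M", [(17, 67)]),  # D consumes reference
            (0, "10M10N10M10N10M", [(10, 20), (30, 40)]),
        ],
    )
    def test_reference_walk(self, pos, cigar, expected):
        assert extract_junctions(make_read(pos=pos, cigar=cigar)) == expected

    @settings(max_examples=200, deadline=None)
    @given(
        pos=st.integers(0, 1000),
        ops=st.lists(
            st.tuples(
                st.sampled_from("MIDNS=X"), st.integers(1, 50)
            ),
            min_size=1,
            max_size=8,
        ),
    )
    def test_agrees_with_bruteforce_reference_expansion(self, pos, ops):
        # normalise into a structurally valid CIGAR: must start/end with
        # an alignment match block and keep S only at the ends
        ops = [("M", 10)] + [(o, n) for o, n in ops if o not in "S"] + [("M", 10)]
        cigar = "".join(f"{n}{o}" for o, n in ops)
        read = make_read(pos=pos, cigar=cigar)
        # oracle: walk the CIGAR string independently, tracking the
        # reference cursor and recording each N gap's span
        cursor = pos
        expected = []
        for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
            n = int(n)
            if op == "N":
                expected.append((cursor, cursor + n))
                cursor += n
            elif op in "MD=X":
                cursor += n
        assert extract_junctions(read) == expected


@pytest.fixture
def index() -> SpliceSiteIndex:
    # two exons 100-200, 300-400 with intron 200-300
    return SpliceSiteIndex(
        [make_transcript([(100, 200), (300, 400), (500, 600)])]
    )


class TestClassifyRead:
    def test_spliced_read_matching_annotated_intron(self, index):
        read = make_read(pos=180, cigar="20M100N20M")
        assert classify_read(read, index) is ReadClass.EXON_EXON_JUNCTION

    def test_unspliced_read_inside_intron(self, index):
        read = make_read(pos=220, cigar="50M")
        assert classify_read(read, index) is ReadClass.FULLY_INTRONIC

    def test_unspliced_read_inside_exon_unclassified(self, index):
        read = make_read(pos=120, cigar="50M")
        assert classify_read(read, index) is ReadClass.UNCLASSIFIED

    def test_boundary_spanning_read_is_bridging(self, index):
        read = make_read(pos=180, cigar="50M")  # crosses 200 with 20/30 nt
        assert classify_read(read, index) is ReadClass.EXON_INTRON_BRIDGING

    def test_bridging_needs_minimum_overhang_both_sides(self, index):
        read = make_read(pos=197, cigar="50M")  # 3 nt on the exon side
        assert classify_read(read, index) is not ReadClass.EXON_INTRON_BRIDGING

    def test_junction_precedes_bridging(self, index):
        # spliced read whose left block also crosses a boundary
        read = make_read(pos=150, cigar="60M90N20M")
        assert classify_read(read, index) is ReadClass.EXON_EXON_JUNCTION

    def test_unannotated_chrom_unclassified(self, index):
        read = make_read(chrom="chr2", pos=220, cigar="50M")
        assert classify_read(read, index) is ReadClass.UNCLASSIFIED


class TestCountSample:
    def test_three_reads_one_junction(self, index):
        reads = [
            make_read(name=f"r{i}", pos=180, cigar="20M100N20M") for i in range(3)
        ]
        table = count_sample(reads, index)
        assert table.junction_count("chr1", 200, 300) == 3

    def test_mate_pair_spanning_same_junction_counts_once(self, index):
        mates = [
            make_read(name="frag1", pos=180, cigar="20M100N20M", flag=99),
            make_read(name="frag1", pos=185, cigar="15M100N25M", flag=147),
        ]
        table = count_sample(mates, index)
        assert table.junction_count("chr1", 200, 300) == 1

    def test_low_mapq_read_excluded_and_tallied(self, index):
        reads = [
            make_read(name="good", pos=180, cigar="20M100N20M", mapq=60),
            make_read(name="bad", pos=180, cigar="20M100N20M", mapq=5),
        ]
        table = count_sample(reads, index, ReadFilters(min_mapq=20))
        assert table.junction_count("chr1", 200, 300) == 1
        assert table.qc["reads_filtered"] == 1

    def test_short_anchor_junction_not_counted(self, index):
        table = count_sample(
            [make_read(pos=196, cigar="4M100N20M")], index, ReadFilters()
        )
        assert table.junction_count("chr1", 200, 300) == 0

    def test_partition_property(self, index):
        reads = [
            make_read(name="a", pos=180, cigar="20M100N20M"),
            make_read(name="b", pos=220, cigar="50M"),
            make_read(name="c", pos=120, cigar="50M"),
            make_read(name="d", pos=180, cigar="50M"),
            make_read(name="e", pos=180, cigar="20M100N20M", mapq=1),
        ]
        qc = count_sample(reads, index).qc
        assert qc["reads_seen"] == qc["reads_passed"] + qc["reads_filtered"]
        assert qc["reads_passed"] == sum(
            qc[c.value] for c in ReadClass
        )

    def test_counting_is_additive_over_disjoint_streams(self, index):
        r1 = [make_read(name="a", pos=180, cigar="20M100N20M")]
        r2 = [make_read(name="b", pos=380, cigar="20M100N20M")]
        t1 = count_sample(r1, index)
        t2 = count_sample(r2, index)
        both = count_sample(r1 + r2, index)
        merged = t1.merge(t2)
        assert both.junction_counts == merged.junction_counts

    def test_intron_depth_from_intronic_reads(self, index):
        reads = [make_read(name=f"r{i}", pos=210, cigar="80M") for i in range(2)]
        table = count_sample(reads, index)
        cov, depth = table.intron_depth[("chr1", 200, 300)]
        assert cov == pytest.approx(0.8)
        assert depth == pytest.approx(1.6)


class TestSjTable:
    def test_star_dialect_conversion(self, tmp_path):
        p = tmp_path / "SJ.out.tab"
        p.write_text("chr1\t201\t300\t1\t1\t1\t15\t3\t25\n")
        table = read_sj_table(p)
        assert table.junction_counts == {("chr1", 200, 300, "+"): 15}

    def test_multimappers_optional(self, tmp_path):
        p = tmp_path / "SJ.out.tab"
        p.write_text("chr1\t201\t300\t2\t1\t1\t15\t3\t25\n")
        assert read_sj_table(p, include_multimappers=True).junction_counts == {
            ("chr1", 200, 300, "-"): 18
        }

    def test_undefined_strand_resolved_from_annotation_else_dropped(
        self, tmp_path, index
    ):
        p = tmp_path / "SJ.out.tab"
        p.write_text("chr1\t201\t300\t0\t0\t1\t7\t0\t20\n")
        assert read_sj_table(p).junction_counts == {}
        assert read_sj_table(p, index).junction_counts == {
            ("chr1", 200, 300, "+"): 7
        }

    def test_wrong_column_count_names_line(self, tmp_path):
        p = tmp_path / "SJ.out.tab"
        p.write_text("chr1\t201\t300\t1\n")
        with pytest.raises(ValueError, match=":1:"):
            read_sj_table(p)

    def test_empty_file_empty_table(self, tmp_path):
        p = tmp_path / "SJ.out.tab"
        p.write_text("")
        assert read_sj_table(p).junction_counts == {}


def test_count_table_tsv_round_trip(tmp_path, index):
    reads = [
        make_read(name="a", pos=180, cigar="20M100N20M"),
        make_read(name="b", pos=180, cigar="50M"),
        make_read(name="c", pos=220, cigar="60M"),
    ]
    table = count_sample(reads, index, sample_id="s1")
    p1, p2 = tmp_path / "c1.tsv", tmp_path / "c2.tsv"
    write_count_table(table, p1)
    back = read_count_table(p1)
    assert back.junction_counts == table.junction_counts
    assert back.bridging_counts == table.bridging_counts
    assert back.intron_depth == table.intron_depth
    write_count_table(back, p2)
    assert p1.read_bytes() == p2.read_bytes()
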