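import itertools
import logging

import numpy as np
import pytest

from natscan.annotation import GenomeAnnotation, Interval, compute_overlap_free_zone
from natscan.contig_qc import ContigRecord
from natscan.strand_reads import (
    AlignmentRecord,
    FragmentAssignment,
    SampleMeta,
    build_count_matrices,
    classify_fragment,
    fragment_strand,
    is_uniquely_mapped,
    parse_sam,
)

from .conftest import make_gene

SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr1\tLN:100000\n"


def write_sam(tmp_path, records, name="test.sam"):
    p = tmp_path / name
    p.write_text(SAM_HEADER + "".join(r + "\n" for r in records))
    return p


def sam_line(qname="q1", flag=0, rname="chr1", pos=1, mapq=60, cigar="50M", nh=None):
    tags = [f"NH:i:{nh}"] if nh is not None else []
    return "\t".join(
        [qname, str(flag), rname, str(pos), str(mapq), cigar, "*", "0", "0", "*", "*"] + tags
    )


class TestParseSam:
    def test_flag_16_is_reverse(self, tmp_path):
        p = write_sam(tmp_path, [sam_line(flag=16)])
        (rec,) = parse_sam(p)
        assert rec.is_reverse

    def test_cigar_ref_length(self, tmp_path):
        p = write_sam(tmp_path, [sam_line(cigar="30M2D18M")])
        (rec,) = parse_sam(p)
        assert rec.aln_len == 50

    def test_soft_clips_do_not_consume_reference(self, tmp_path):
        p = write_sam(tmp_path, [sam_line(cigar="5S40M5S")])
        (rec,) = parse_sam(p)
        assert rec.aln_len == 40

    def test_pos_is_zero_based(self, tmp_path):
        p = write_sam(tmp_path, [sam_line(pos=101)])
        (rec,) = parse_sam(p)
        assert rec.pos == 100

    def test_unmapped_secondary_supplementary_skipped(self, tmp_path):
        p = write_sam(tmp_path, [
            sam_line(qname="u", flag=4),
            sam_line(qname="s", flag=256),
            sam_line(qname="sup", flag=2048),
            sam_line(qname="ok", flag=0),
        ])
        recs = list(parse_sam(p))
        assert [r.qname for r in recs] == ["ok"]

    def test_bad_cigar_skipped_with_warning(self, tmp_path, caplog):
        p = write_sam(tmp_path, [sam_line(qname="bad", cigar="xyz"), sam_line(qname="ok")])
        with caplog.at_level(logging.WARNING):
            recs = list(parse_sam(p))
        assert [r.qname for r in recs] == ["ok"]
        assert any("skipped" in r.message for r in caplog.records)

    def test_nh_tag_captured(self, tmp_path):
        p = write_sam(tmp_path, [sam_line(nh=3), sam_line(qname="q2")])
        recs = list(parse_sam(p))
        assert recs[0].nh == 3
        assert recs[1].nh is None

    def test_round_trip_random_records(self, tmp_path, rng):
        lines, expected = [], []
        for i in range(100):
            pos = int(rng.integers(1, 5000))
            rev = bool(rng.random() < 0.5)
            mate1 = bool(rng.random() < 0.5)
            flag = (0x10 if rev else 0) | (0x40 if mate1 else 0x80) | 0x1
            mapq = int(rng.integers(0, 61))
            nh = int(rng.integers(1, 4))
            aln = int(rng.integers(20, 150))
            lines.append(sam_line(f"q{i}", flag, "chr1", pos, mapq, f"{aln}M", nh))
            expected.append((f"q{i}", pos - 1, aln, rev, mate1, mapq, nh))
        p = write_sam(tmp_path, lines)
        recs = list(parse_sam(p))
        got = [(r.qname, r.pos, r.aln_len, r.is_reverse, r.is_read1, r.mapq, r.nh)
               for r in recs]
        assert got == [(q, p_, a, r, m, mq, nh) for q, p_, a, r, m, mq, nh in expected]


class TestFragmentStrand:
    def test_rf_read1_forward(self):
        rec = AlignmentRecord("q", "chr1", 0, 50, is_reverse=False,
                              is_read1=True, is_read2=False, mapq=60)
        assert fragment_strand(rec, "RF") == "-"

    def test_rf_read2_forward(self):
        rec = AlignmentRecord("q", "chr1", 0, 50, is_reverse=False,
                              is_read1=False, is_read2=True, mapq=60)
        assert fragment_strand(rec, "RF") == "+"

    def test_exhaustive_truth_table(self):
        # hand-enumerated: RF read1 flips, RF read2 keeps; FR is the mirror
        truth = {
            ("RF", "read1", "+"): "-", ("RF", "read1", "-"): "+",
            ("RF", "read2", "+"): "+", ("RF", "read2", "-"): "-",
            ("FR", "read1", "+"): "+", ("FR", "read1", "-"): "-",
            ("FR", "read2", "+"): "-", ("FR", "read2", "-"): "+",
        }
        for protocol, mate, aln in itertools.product(
            ["RF", "FR"], ["read1", "read2"], ["+", "-"]
        ):
            rec = AlignmentRecord(
                "q", "chr1", 0, 50,
                is_reverse=aln == "-",
                is_read1=mate == "read1",
                is_read2=mate == "read2",
                mapq=60,
            )
            assert fragment_strand(rec, protocol) == truth[(protocol, mate, aln)], (
                protocol, mate, aln,
            )

    def test_single_end_treated_as_read1(self):
        rec = AlignmentRecord("q", "chr1", 0, 50, is_reverse=False,
                              is_read1=False, is_read2=False, mapq=60)
        assert fragment_strand(rec, "RF") == "-"

    def test_unknown_protocol(self):
        rec = AlignmentRecord("q", "chr1", 0, 50, is_reverse=False,
                              is_read1=True, is_read2=False, mapq=60)
        with pytest.raises(ValueError, match="protocol"):
            fragment_strand(rec, "XX")


class TestUniquelyMapped:
    @pytest.mark.parametrize(
        "nh,mapq,min_mapq,expected",
        [
            (1, 0, 30, True),     # NH authoritative
            (None, 3, 30, False),
            (2, 255, 30, False),
            (None, 30, 30, True),  # MAPQ fallback inclusive
        ],
    )
    def test_rule(self, nh, mapq, min_mapq, expected):
        rec = AlignmentRecord("q", "chr1", 0, 50, is_reverse=False,
                              is_read1=True, is_read2=False, mapq=mapq, nh=nh)
        assert is_uniquely_mapped(rec, min_mapq=min_mapq) is expected


def _rec(pos, aln_len=50, reverse=False, read1=True, seq_id="chr1", nh=1):
    return AlignmentRecord("q", seq_id, pos, aln_len, is_reverse=reverse,
                           is_read1=read1, is_read2=not read1, mapq=255, nh=nh)


class TestClassifyFragment:
    @pytest.fixture
    def setup(self, two_gene_annotation):
        gene = two_gene_annotation["X"]  # + strand [100,1000), zone [100,400)+[600,1000)
        zone = compute_overlap_free_zone(gene, two_gene_annotation)
        return gene, zone

    def test_antisense_inside_zone(self, setup):
        gene, zone = setup
        # read1 forward => fragment '-' under RF => antisense to + gene
        a = classify_fragment(_rec(150, reverse=False, read1=True), gene, zone)
        assert a.orientation == "antisense"

    def test_antisense_inside_blocker_is_outside_zone(self, setup):
        gene, zone = setup
        a = classify_fragment(_rec(450, reverse=False, read1=True), gene, zone)
        assert a.orientation == "outside_zone"

    def test_sense(self, setup):
        gene, zone = setup
        a = classify_fragment(_rec(150, reverse=True, read1=True), gene, zone)
        assert a.orientation == "sense"

    def test_no_span_overlap_is_ambiguous(self, setup):
        gene, zone = setup
        a = classify_fragment(_rec(5000, reverse=True, read1=True), gene, zone)
        assert a.orientation == "ambiguous"

    def test_seq_mismatch_raises(self, setup):
        gene, zone = setup
        with pytest.raises(ValueError, match="chr2"):
            classify_fragment(_rec(150, seq_id="chr2"), gene, zone)

    def test_mate_swap_invariance(self, setup, rng):
        gene, zone = setup
        for _ in range(200):
            pos = int(rng.integers(0, 1200))
            rev1 = bool(rng.random() < 0.5)
            r1 = _rec(pos, reverse=rev1, read1=True)
            r2 = _rec(pos, reverse=not rev1, read1=False)  # opposite-orientation mate
            a1 = classify_fragment(r1, gene, zone)
            a2 = classify_fragment(r2, gene, zone)
            assert a1.orientation == a2.orientation


class TestBuildCountMatrices:
    SAMPLES = [SampleMeta("s1", "mPFC", 7, 1), SampleMeta("s2", "striatum", 7, 1)]

    def _assign(self, qname, gene, orientation, unique=True, start=0, end=50):
        return FragmentAssignment(qname, gene, orientation, unique,
                                  Interval("chr1", start, end))

    def test_mates_deduplicated(self):
        a = [self._assign("f1", "X", "sense"), self._assign("f1", "X", "sense")]
        sense, anti = build_count_matrices({"s1": a}, self.SAMPLES)
        assert sense.counts.loc["X", "s1"] == 1

    def test_empty_stream(self):
        sense, anti = build_count_matrices({}, self.SAMPLES, gene_ids=["X"])
        assert (sense.counts.to_numpy() == 0).all()
        assert anti.counts.empty or (anti.counts.to_numpy() == 0).all()

    def test_non_unique_not_counted(self):
        a = [self._assign("f1", "X", "sense", unique=False)]
        sense, _ = build_count_matrices({"s1": a}, self.SAMPLES)
        assert sense.counts.loc["X", "s1"] == 0

    def test_antisense_assigned_to_intersecting_contigs(self):
        contigs = [
            ContigRecord("c1", "X", [Interval("chr1", 0, 100)], length=100),
            ContigRecord("c2", "X", [Interval("chr1", 200, 300)], length=100),
        ]
        a = [self._assign("f1", "X", "antisense", start=10, end=60)]
        _, anti = build_count_matrices({"s1": a}, self.SAMPLES, contigs)
        assert anti.counts.loc["c1", "s1"] == 1
        assert anti.counts.loc["c2", "s1"] == 0

    def test_multi_contig_fragment_counted_for_each(self):
        contigs = [
            ContigRecord("c1", "X", [Interval("chr1", 0, 100)], length=100),
            ContigRecord("c2", "X", [Interval("chr1", 40, 140)], length=100),
        ]
        a = [self._assign("f1", "X", "antisense", start=45, end=95)]
        _, anti = build_count_matrices({"s1": a}, self.SAMPLES, contigs)
        assert anti.counts.loc["c1", "s1"] == 1
        assert anti.counts.loc["c2", "s1"] == 1

    def test_unknown_sample_rejected(self):
        with pytest.raises(ValueError, match="unknown samples"):
            build_count_matrices({"nope": []}, self.SAMPLES)

    def test_per_contig_counts_bounded_by_gene_antisense_total(self, rng):
        contigs = [
            ContigRecord("c1", "X", [Interval("chr1", 0, 500)], length=500),
            ContigRecord("c2", "X", [Interval("chr1", 100, 400)], length=300),
        ]
        assigns = []
        n_anti = 0
        for i in range(100):
            start = int(rng.integers(0, 600))
            orient = "antisense" if rng.random() < 0.6 else "sense"
            n_anti += orient == "antisense"
            assigns.append(self._assign(f"f{i}", "X", orient, start=start, end=start + 50))
        _, anti = build_count_matrices({"s1": assigns}, self.SAMPLES, contigs)
        assert (anti.counts["s1"] <= n_anti).all()
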