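import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from natscan.annotation import (
    AnnotationError,
    GTFParseError,
    GenomeAnnotation,
    Interval,
    compute_overlap_free_zone,
    load_annotation,
    merge_intervals,
    subtract_intervals,
    write_contig_gtf,
)
from natscan.contig_qc import ContigRecord

from .conftest import brute_force_zone_mask, make_gene, random_annotation, zones_to_mask


class TestInterval:
    def test_invariants(self):
        with pytest.raises(AnnotationError):
            Interval("chr1", -1, 5)
        with pytest.raises(AnnotationError):
            Interval("chr1", 5, 5)

    def test_intersects(self):
        a = Interval("chr1", 0, 10)
        assert a.intersects(Interval("chr1", 9, 20))
        assert not a.intersects(Interval("chr1", 10, 20))  # half-open adjacency
        assert not a.intersects(Interval("chr2", 0, 10))


class TestLoadAnnotation:
    def _write(self, tmp_path, lines):
        p = tmp_path / "test.gtf"
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_coordinate_conversion(self, tmp_path):
        # exons 101-200 and 301-400 (1-based closed) -> span [100,400)
        p = self._write(tmp_path, [
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1";',
            'chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "g1";',
        ])
        ann = load_annotation(p)
        g = ann["g1"]
        assert (g.span.start, g.span.end) == (100, 400)
        assert [(e.start, e.end) for e in g.exons] == [(100, 200), (300, 400)]

    def test_empty_file_warns(self, tmp_path, caplog):
        p = tmp_path / "empty.gtf"
        p.write_text("")
        with caplog.at_level(logging.WARNING):
            ann = load_annotation(p)
        assert len(ann) == 0
        assert any("no features" in r.message for r in caplog.records)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = self._write(tmp_path, [
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1";',
            "chr1\tonly\tthree",
        ])
        with pytest.raises(GTFParseError, match=":2:"):
            load_annotation(p)

    def test_non_integer_coordinates(self, tmp_path):
        p = self._write(tmp_path, ['chr1\tsrc\texon\tabc\t200\t.\t+\t.\tgene_id "g1";'])
        with pytest.raises(GTFParseError, match=":1:"):
            load_annotation(p)

    def test_unknown_strand_rejected_with_gene_id(self, tmp_path):
        p = self._write(tmp_path, ['chr1\tsrc\texon\t101\t200\t.\t.\t.\tgene_id "gX";'])
        with pytest.raises(AnnotationError, match="gX"):
            load_annotation(p)

    def test_round_trip_random_genes(self, tmp_path, rng):
        # independent writer: emit GTF text directly, then reload
        genes = {}
        lines = []
        for i in range(50):
            start1 = int(rng.integers(1, 9000))  # 1-based closed
            end1 = start1 + int(rng.integers(50, 900))
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"rt{i}"
            genes[gid] = (start1 - 1, end1, strand)
            lines.append(
                f'chr1\tsrc\texon\t{start1}\t{end1}\t.\t{strand}\t.\tgene_id "{gid}";'
            )
        p = self._write(tmp_path, lines)
        ann = load_annotation(p)
        assert len(ann) == 50
        for gid, (start0, end0, strand) in genes.items():
            g = ann[gid]
            assert (g.span.start, g.span.end, g.strand) == (start0, end0, strand)


class TestOverlapFreeZone:
    def test_simple_subtraction(self, two_gene_annotation):
        z = compute_overlap_free_zone(two_gene_annotation["X"], two_gene_annotation)
        assert [(i.start, i.end) for i in z.zones] == [(100, 400), (600, 1000)]

    def test_no_opposite_overlap_keeps_span(self):
        ann = GenomeAnnotation([make_gene("A", 0, 500, "+"), make_gene("B", 100, 300, "+")])
        z = compute_overlap_free_zone(ann["A"], ann)
        assert [(i.start, i.end) for i in z.zones] == [(0, 500)]

    def test_fully_blocked_gene_has_empty_zone(self):
        ann = GenomeAnnotation([make_gene("A", 100, 300, "+"), make_gene("B", 0, 500, "-")])
        z = compute_overlap_free_zone(ann["A"], ann)
        assert z.zones == []

    def test_gene_not_in_annotation(self, two_gene_annotation):
        orphan = make_gene("Z", 0, 100, "+")
        with pytest.raises(KeyError, match="Z"):
            compute_overlap_free_zone(orphan, two_gene_annotation)

    def test_blocker_biotype_config(self):
        ann = GenomeAnnotation([
            make_gene("A", 0, 500, "+"),
            make_gene("B", 100, 200, "-", biotype="lncRNA"),
        ])
        z_all = compute_overlap_free_zone(ann["A"], ann)
        assert z_all.total_length() == 400
        z_pc = compute_overlap_free_zone(ann["A"], ann, blocker_biotypes={"protein_coding"})
        assert z_pc.total_length() == 500

    def test_random_annotations_match_per_base_oracle(self, rng):
        for _ in range(200):
            ann = random_annotation(rng)
            for gene in ann:
                z = compute_overlap_free_zone(gene, ann)
                assert zones_to_mask(z) == brute_force_zone_mask(gene, ann)

    def test_idempotent(self, rng):
        for _ in range(20):
            ann = random_annotation(rng)
            for gene in ann:
                z1 = compute_overlap_free_zone(gene, ann)
                # re-subtracting the same blockers from each zone changes nothing
                blockers = [
                    o.span for o in ann
                    if o.gene_id != gene.gene_id and o.strand != gene.strand
                ]
                again = [
                    part for z in z1.zones for part in subtract_intervals(z, blockers)
                ]
                assert [(i.start, i.end) for i in again] == [
                    (i.start, i.end) for i in z1.zones
                ]

    def test_zone_length_bound(self, rng):
        for _ in range(50):
            ann = random_annotation(rng)
            for gene in ann:
                z = compute_overlap_free_zone(gene, ann)
                has_opposite_overlap = any(
                    o.gene_id != gene.gene_id
                    and o.strand != gene.strand
                    and o.span.intersects(gene.span)
                    for o in ann
                )
                if has_opposite_overlap:
                    assert z.total_length() < len(gene.span)
                else:
                    assert z.total_length() == len(gene.span)


class TestIntervalIndex:
    def test_index_equals_linear_scan(self, rng):
        for _ in range(50):
            ann = random_annotation(rng)
            for _ in range(10):
                start = int(rng.integers(0, 10_000))
                end = start + int(rng.integers(1, 2000))
                q = Interval("chr1", start, end)
                got = {g.gene_id for g in ann.overlapping(q)}
                want = {g.gene_id for g in ann if g.span.intersects(q)}
                assert got == want

    def test_duplicate_gene_id_rejected(self):
        ann = GenomeAnnotation([make_gene("A", 0, 10)])
        with pytest.raises(AnnotationError, match="duplicate"):
            ann.add(make_gene("A", 20, 30))


@st.composite
def interval_lists(draw):
    n = draw(st.integers(min_value=0, max_value=8))
    out = []
    for _ in range(n):
        s = draw(st.integers(min_value=0, max_value=500))
        length = draw(st.integers(min_value=1, max_value=200))
        out.append(Interval("chr1", s, s + length))
    return out


@settings(max_examples=100, deadline=None)
@given(base_start=st.integers(0, 300), base_len=st.integers(1, 300), blockers=interval_lists())
def test_subtract_intervals_property(base_start, base_len, blockers):
    base = Interval("chr1", base_start, base_start + base_len)
    result = subtract_intervals(base, blockers)
    expected = [
        p for p in range(base.start, base.end)
        if not any(b.contains_point(p) for b in blockers)
    ]
    got = [p for iv in result for p in range(iv.start, iv.end)]
    assert got == expected
    # disjoint, sorted, non-adjacent (separated by at least one blocked base)
    for a, b in zip(result, result[1:]):
        assert a.end < b.start


@settings(max_examples=100, deadline=None)
@given(intervals=interval_lists())
def test_merge_intervals_property(intervals):
    merged = merge_intervals(intervals)
    want = sorted({p for iv in intervals for p in range(iv.start, iv.end)})
    got = [p for iv in merged for p in range(iv.start, iv.end)]
    assert got == want


class TestWriteContigGtf:
    def test_two_segment_contig(self, tmp_path, two_gene_annotation):
        contig = ContigRecord(
            "c1", "X",
            [Interval("chr1", 110, 150), Interval("chr1", 170, 190)],
            length=60,
        )
        out = tmp_path / "contigs.gtf"
        write_contig_gtf([contig], two_gene_annotation, out)
        lines = [l.split("\t") for l in out.read_text().splitlines()]
        assert [l[2] for l in lines] == ["transcript", "exon", "exon"]
        assert all(l[6] == "-" for l in lines)  # opposite of gene X (+)
        assert [(l[3], l[4]) for l in lines[1:]] == [("111", "150"), ("171", "190")]

    def test_single_segment(self, tmp_path, two_gene_annotation):
        contig = ContigRecord("c1", "Y", [Interval("chr1", 450, 550)], length=100)
        out = tmp_path / "one.gtf"
        write_contig_gtf([contig], two_gene_annotation, out)
        lines = out.read_text().splitlines()
        assert len(lines) == 2  # transcript + one exon
        assert lines[1].split("\t")[6] == "+"  # opposite of gene Y (-)

    def test_segment_outside_span_warns_but_written(self, tmp_path, two_gene_annotation, caplog):
        contig = ContigRecord("c1", "X", [Interval("chr1", 5000, 5100)], length=100)
        out = tmp_path / "warn.gtf"
        with caplog.at_level(logging.WARNING):
            write_contig_gtf([contig], two_gene_annotation, out)
        assert any("outside cognate gene" in r.message for r in caplog.records)
        assert "exon" in out.read_text()

    def test_contig_without_segments_rejected(self, tmp_path, two_gene_annotation):
        contig = ContigRecord("c1", "X", [Interval("chr1", 0, 1)], length=1)
        contig.segments = []
        with pytest.raises(AnnotationError, match="c1"):
            write_contig_gtf([contig], two_gene_annotation, tmp_path / "x.gtf")

    def test_round_trip_random_contigs(self, tmp_path, rng):
        genes = [make_gene(f"g{i}", i * 2000, i * 2000 + 1500,
                           "+" if i % 2 else "-") for i in range(20)]
        ann = GenomeAnnotation(genes)
        contigs = []
        for i, g in enumerate(genes):
            n_seg = int(rng.integers(1, 4))
            segs = []
            pos = g.span.start + 10
            for _ in range(n_seg):
                seg_len = int(rng.integers(20, 120))
                segs.append(Interval("chr1", pos, pos + seg_len))
                pos += seg_len + int(rng.integers(10, 50))
            contigs.append(ContigRecord(f"c{i}", g.gene_id, segs,
                                        length=sum(len(s) for s in segs)))
        out = tmp_path / "rt.gtf"
        write_contig_gtf(contigs, ann, out)
        reloaded = load_annotation(out)
        assert len(reloaded) == 20
        for c in contigs:
            got = [(e.start, e.end) for e in reloaded[c.contig_id].exons]
            want = sorted((s.start, s.end) for s in c.segments)
            assert got == want
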