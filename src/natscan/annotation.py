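"""Gene annotation handling: GTF I/O, gene spans and overlap-free zones.

Internal coordinates are 0-based half-open throughout; GTF input/output
converts to and from the 1-based closed convention on the fly.

A gene's *overlap-free zone* is the part of its span not covered by any
other annotated gene on the opposite strand.  Antisense reads are only
attributable to a gene inside this zone.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Interval",
    "GeneModel",
    "GenomeAnnotation",
    "OverlapFreeZone",
    "AnnotationError",
    "GTFParseError",
    "load_annotation",
    "compute_overlap_free_zone",
    "subtract_intervals",
    "merge_intervals",
    "write_contig_gtf",
]


class AnnotationError(ValueError):
    """Raised for semantically invalid annotation content."""


class GTFParseError(AnnotationError):
    """Raised for a syntactically malformed GTF line; names the line number."""


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open genomic interval [start, end) on a named sequence."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise AnnotationError(f"interval start {self.start} < 0")
        if self.end <= self.start:
            raise AnnotationError(
                f"interval end {self.end} must exceed start {self.start}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def intersects(self, other: "Interval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class GeneModel:
    """One gene: UTR-inclusive span plus the feature intervals it came from."""

    gene_id: str
    seq_id: str
    strand: str
    span: Interval
    biotype: str = "protein_coding"
    exons: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.span.seq_id != self.seq_id:
            raise AnnotationError(
                f"gene {self.gene_id!r}: span on {self.span.seq_id}, gene on {self.seq_id}"
            )


class _IntervalIndex:
    """Sorted-start interval index for one sequence.

    Query walks candidates whose start precedes the query end and prunes
    with a running maximum of ends, which is adequate at annotation scale
    and trivially checkable against a linear scan.
    """

    def __init__(self, items: Iterable[tuple[Interval, str]]):
        entries = sorted(items, key=lambda it: (it[0].start, it[0].end))
        self._starts = [iv.start for iv, _ in entries]
        self._entries = entries
        # cummax[i] = max end over entries[0..i]; lets queries stop early
        self._cummax: list[int] = []
        running = 0
        for iv, _ in entries:
            running = max(running, iv.end)
            self._cummax.append(running)

    def query(self, start: int, end: int) -> list[str]:
        hi = bisect.bisect_left(self._starts, end)
        out = []
        for i in range(hi - 1, -1, -1):
            if self._cummax[i] <= start:
                break
            iv, gid = self._entries[i]
            if iv.end > start:
                out.append(gid)
        out.reverse()
        return out


class GenomeAnnotation:
    """Collection of :class:`GeneModel` indexed by id and by genomic interval."""

    def __init__(self, genes: Iterable[GeneModel] = ()):
        self._genes: dict[str, GeneModel] = {}
        self._index: dict[str, _IntervalIndex] | None = None
        for g in genes:
            self.add(g)

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self._genes:
            raise AnnotationError(f"duplicate gene_id {gene.gene_id!r}")
        self._genes[gene.gene_id] = gene
        self._index = None

    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._genes.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        try:
            return self._genes[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in annotation") from None

    def get(self, gene_id: str) -> GeneModel | None:
        return self._genes.get(gene_id)

    @property
    def gene_ids(self) -> list[str]:
        return list(self._genes)

    def _build_index(self) -> dict[str, _IntervalIndex]:
        if self._index is None:
            by_seq: dict[str, list[tuple[Interval, str]]] = {}
            for g in self._genes.values():
                by_seq.setdefault(g.seq_id, []).append((g.span, g.gene_id))
            self._index = {s: _IntervalIndex(items) for s, items in by_seq.items()}
        return self._index

    def overlapping(self, region: Interval) -> list[GeneModel]:
        """All genes whose span intersects *region* (either strand)."""
        idx = self._build_index().get(region.seq_id)
        if idx is None:
            return []
        return [self._genes[gid] for gid in idx.query(region.start, region.end)]


@dataclass
class OverlapFreeZone:
    """Disjoint sorted sub-intervals of a gene span free of opposite-strand genes."""

    gene_id: str
    zones: list[Interval]

    def __post_init__(self) -> None:
        for a, b in zip(self.zones, self.zones[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"zones for {self.gene_id!r} overlap or are unsorted"
                )

    def intersects(self, iv: Interval) -> bool:
        return any(z.intersects(iv) for z in self.zones)

    def total_length(self) -> int:
        return sum(len(z) for z in self.zones)


# ---------------------------------------------------------------------------
# GTF I/O

_GTF_COLUMNS = 9


def _parse_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def load_annotation(gtf_path: str | Path) -> GenomeAnnotation:
    """Load a GTF file into a :class:`GenomeAnnotation`.

    Gene spans are the union extent (min start to max end) over every
    feature carrying the same ``gene_id``; per-feature intervals are kept
    as ``exons`` for round-tripping.  Coordinates convert from 1-based
    closed to 0-based half-open.

    Raises
    ------
    GTFParseError
        On a malformed line, naming its 1-based line number.
    AnnotationError
        When a gene has no usable strand or inconsistent placement.
    """
    gtf_path = Path(gtf_path)
    per_gene: dict[str, dict] = {}
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _GTF_COLUMNS:
                raise GTFParseError(
                    f"{gtf_path}:{lineno}: expected {_GTF_COLUMNS} tab-separated "
                    f"fields, got {len(fields)}"
                )
            seq_id, _source, _feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GTFParseError(
                    f"{gtf_path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            if start1 < 1 or end1 < start1:
                raise GTFParseError(
                    f"{gtf_path}:{lineno}: invalid coordinate range {start1}-{end1}"
                )
            attrs = _parse_attributes(attr_s)
            gene_id = attrs.get("gene_id")
            if not gene_id:
                raise GTFParseError(f"{gtf_path}:{lineno}: missing gene_id attribute")
            if strand not in ("+", "-"):
                raise AnnotationError(
                    f"gene {gene_id!r}: unknown strand symbol {strand!r} "
                    f"at {gtf_path}:{lineno}"
                )
            iv = Interval(seq_id, start1 - 1, end1)
            entry = per_gene.setdefault(
                gene_id,
                {"seq_id": seq_id, "strand": strand, "features": [],
                 "biotype": attrs.get("gene_biotype", attrs.get("gene_type", "unknown"))},
            )
            if entry["seq_id"] != seq_id or entry["strand"] != strand:
                raise AnnotationError(
                    f"gene {gene_id!r}: inconsistent seq/strand across features "
                    f"(line {lineno})"
                )
            entry["features"].append((iv, _feature))

    if not per_gene:
        logger.warning("GTF file %s contained no features; empty annotation", gtf_path)
        return GenomeAnnotation()

    genes = []
    for gene_id, entry in per_gene.items():
        ivs = [iv for iv, _ in entry["features"]]
        span = Interval(
            entry["seq_id"], min(iv.start for iv in ivs), max(iv.end for iv in ivs)
        )
        exon_ivs = sorted(
            {iv for iv, feat in entry["features"] if feat == "exon"},
            key=lambda iv: (iv.start, iv.end),
        )
        genes.append(
            GeneModel(
                gene_id=gene_id,
                seq_id=entry["seq_id"],
                strand=entry["strand"],
                span=span,
                biotype=entry["biotype"],
                exons=exon_ivs,
            )
        )
    return GenomeAnnotation(genes)


# ---------------------------------------------------------------------------
# Interval arithmetic


def merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Union of intervals (same seq assumed) as sorted disjoint intervals."""
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = Interval(last.seq_id, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def subtract_intervals(base: Interval, blockers: Sequence[Interval]) -> list[Interval]:
    """``base`` minus the union of ``blockers`` (same seq_id assumed)."""
    relevant = [b for b in blockers if b.intersects(base)]
    if not relevant:
        return [base]
    result: list[Interval] = []
    cursor = base.start
    for b in merge_intervals(relevant):
        if b.start > cursor:
            result.append(Interval(base.seq_id, cursor, min(b.start, base.end)))
        cursor = max(cursor, b.end)
        if cursor >= base.end:
            break
    if cursor < base.end:
        result.append(Interval(base.seq_id, cursor, base.end))
    return result


def compute_overlap_free_zone(
    gene: GeneModel,
    annotation: GenomeAnnotation,
    blocker_biotypes: set[str] | None = None,
    min_zone_length: int = 1,
) -> OverlapFreeZone:
    """Subtract opposite-strand gene spans from ``gene``'s span.

    Parameters
    ----------
    blocker_biotypes
        If given, only opposite-strand genes with one of these biotypes
        shrink the zone; default: every annotated gene blocks.
    min_zone_length
        Zones shorter than this are dropped.
    """
    if gene.gene_id not in annotation:
        raise KeyError(f"gene {gene.gene_id!r} not in annotation")
    blockers = [
        other.span
        for other in annotation.overlapping(gene.span)
        if other.gene_id != gene.gene_id
        and other.strand != gene.strand
        and (blocker_biotypes is None or other.biotype in blocker_biotypes)
    ]
    zones = [
        z for z in subtract_intervals(gene.span, blockers) if len(z) >= min_zone_length
    ]
    return OverlapFreeZone(gene_id=gene.gene_id, zones=zones)


def write_contig_gtf(contigs, annotation: GenomeAnnotation, out_path: str | Path) -> None:
    """Write antisense contigs as GTF transcripts with one exon per segment.

    The emitted strand is the opposite of the cognate gene's strand.
    Segments falling outside the cognate gene span are still written, with
    a warning.  Output is re-loadable by :func:`load_annotation`.
    """
    out_path = Path(out_path)
    lines = []
    for contig in contigs:
        if not contig.segments:
            raise AnnotationError(f"contig {contig.contig_id!r} has no segments")
        gene = annotation[contig.cognate_gene_id]
        strand = "-" if gene.strand == "+" else "+"
        seg_sorted = sorted(contig.segments, key=lambda iv: (iv.start, iv.end))
        first, last = seg_sorted[0], seg_sorted[-1]
        attrs = (
            f'gene_id "{contig.contig_id}"; transcript_id "{contig.contig_id}.t1"; '
            f'cognate_gene_id "{contig.cognate_gene_id}"; gene_biotype "antisense_contig";'
        )
        lines.append(
            "\t".join(
                [
                    first.seq_id, "natscan", "transcript",
                    str(first.start + 1), str(last.end), ".", strand, ".", attrs,
                ]
            )
        )
        for seg in seg_sorted:
            if not seg.intersects(gene.span):
                logger.warning(
                    "contig %s segment [%d,%d) outside cognate gene %s span",
                    contig.contig_id, seg.start, seg.end, gene.gene_id,
                )
            lines.append(
                "\t".join(
                    [
                        seg.seq_id, "natscan", "exon",
                        str(seg.start + 1), str(seg.end), ".", strand, ".", attrs,
                    ]
                )
            )
    out_path.write_text("\n".join(lines) + ("\n" if lines else ""))
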