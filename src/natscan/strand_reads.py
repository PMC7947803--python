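"""Stranded read handling: SAM-text parsing, fragment strand inference,
sense/antisense classification against overlap-free zones, and unique-read
count matrices.

The library protocol follows the dUTP convention (``RF``): read1 aligns
antisense to the source transcript, so the fragment strand is the opposite
of read1's alignment strand (equivalently, read2's alignment strand).
``FR`` is the mirror convention.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .annotation import GeneModel, Interval, OverlapFreeZone

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentRecord",
    "FragmentAssignment",
    "SampleMeta",
    "CountMatrix",
    "parse_sam",
    "fragment_strand",
    "is_uniquely_mapped",
    "classify_fragment",
    "build_count_matrices",
    "read_sample_sheet",
]

# SAM FLAG bits
_FLAG_PAIRED = 0x1
_FLAG_UNMAPPED = 0x4
_FLAG_REVERSE = 0x10
_FLAG_READ1 = 0x40
_FLAG_READ2 = 0x80
_FLAG_SECONDARY = 0x100
_FLAG_SUPPLEMENTARY = 0x800

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = set("MDN=X")


@dataclass(frozen=True)
class AlignmentRecord:
    """One mapped primary alignment from a SAM-text file."""

    qname: str
    seq_id: str
    pos: int  # 0-based leftmost
    aln_len: int  # reference bases consumed (CIGAR M/D/N/=/X)
    is_reverse: bool
    is_read1: bool
    is_read2: bool
    mapq: int
    nh: int | None = None

    def __post_init__(self) -> None:
        if self.aln_len <= 0:
            raise ValueError(f"record {self.qname!r}: aln_len must be positive")
        if self.is_read1 and self.is_read2:
            raise ValueError(f"record {self.qname!r}: both read1 and read2 flags set")

    @property
    def interval(self) -> Interval:
        return Interval(self.seq_id, self.pos, self.pos + self.aln_len)

    @property
    def alignment_strand(self) -> str:
        return "-" if self.is_reverse else "+"


@dataclass(frozen=True)
class FragmentAssignment:
    """Per-gene classification of one fragment."""

    qname: str
    gene_id: str
    orientation: str  # sense | antisense | outside_zone | ambiguous
    unique: bool
    interval: Interval | None = None


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    tissue: str
    age: int  # postnatal day
    replicate: int
    sex: str = "NA"


def _cigar_ref_length(cigar: str) -> int:
    if cigar == "*":
        raise ValueError("missing CIGAR")
    consumed = 0
    pos = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise ValueError(f"unparsable CIGAR {cigar!r}")
        pos = m.end()
        n, op = int(m.group(1)), m.group(2)
        if op in _REF_CONSUMING:
            consumed += n
    if pos != len(cigar):
        raise ValueError(f"unparsable CIGAR {cigar!r}")
    return consumed


def parse_sam(path: str | Path) -> Iterator[AlignmentRecord]:
    """Yield mapped primary records from a SAM-text file.

    Unmapped, secondary and supplementary records are skipped silently;
    records with an unparsable CIGAR are skipped with a logged warning.
    The optional ``NH:i`` tag is captured when present.
    """
    path = Path(path)
    n_skipped = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                n_skipped += 1
                logger.warning("%s: truncated SAM record skipped", path)
                continue
            qname, flag_s, rname, pos_s, mapq_s, cigar = fields[:6]
            flag = int(flag_s)
            if flag & (_FLAG_UNMAPPED | _FLAG_SECONDARY | _FLAG_SUPPLEMENTARY):
                continue
            if rname == "*":
                continue
            try:
                aln_len = _cigar_ref_length(cigar)
            except ValueError as exc:
                n_skipped += 1
                logger.warning("%s: record %s skipped (%s)", path, qname, exc)
                continue
            nh = None
            for tag in fields[11:]:
                if tag.startswith("NH:i:"):
                    nh = int(tag[5:])
                    break
            yield AlignmentRecord(
                qname=qname,
                seq_id=rname,
                pos=int(pos_s) - 1,
                aln_len=aln_len,
                is_reverse=bool(flag & _FLAG_REVERSE),
                is_read1=bool(flag & _FLAG_READ1),
                is_read2=bool(flag & _FLAG_READ2) and not bool(flag & _FLAG_READ1),
                mapq=int(mapq_s),
                nh=nh,
            )
    if n_skipped:
        logger.warning("%s: %d records skipped", path, n_skipped)


def fragment_strand(rec: AlignmentRecord, protocol: str = "RF") -> str:
    """Infer the source-transcript strand of a fragment.

    ``RF`` (dUTP): transcript strand = opposite of read1's alignment
    strand = read2's alignment strand.  ``FR``: the mirror.  Single-end
    records (neither mate flag) are treated as read1.
    """
    if protocol not in ("RF", "FR"):
        raise ValueError(f"unknown protocol {protocol!r}")
    read1_like = rec.is_read1 or not rec.is_read2
    aln = rec.alignment_strand
    if protocol == "RF":
        if read1_like:
            return "-" if aln == "+" else "+"
        return aln
    if read1_like:
        return aln
    return "-" if aln == "+" else "+"


def is_uniquely_mapped(rec: AlignmentRecord, min_mapq: int = 30) -> bool:
    """NH tag authoritative when present; MAPQ threshold otherwise."""
    if rec.nh is not None:
        return rec.nh == 1
    return rec.mapq >= min_mapq


def classify_fragment(
    rec: AlignmentRecord,
    gene: GeneModel,
    zone: OverlapFreeZone,
    protocol: str = "RF",
    min_mapq: int = 30,
) -> FragmentAssignment:
    """Classify one fragment against one gene.

    sense
        fragment strand equals gene strand and the fragment overlaps the
        gene span;
    antisense
        fragment strand opposite and the fragment overlaps the gene's
        overlap-free zone;
    outside_zone
        strand opposite, overlaps the span, but misses every zone;
    ambiguous
        anything else (no span overlap).
    """
    if rec.seq_id != gene.seq_id:
        raise ValueError(
            f"record {rec.qname!r} on {rec.seq_id}, gene {gene.gene_id!r} on {gene.seq_id}"
        )
    strand = fragment_strand(rec, protocol)
    frag_iv = rec.interval
    in_span = frag_iv.intersects(gene.span)
    unique = is_uniquely_mapped(rec, min_mapq=min_mapq)
    if strand == gene.strand:
        orientation = "sense" if in_span else "ambiguous"
    elif zone.intersects(frag_iv):
        orientation = "antisense"
    elif in_span:
        orientation = "outside_zone"
    else:
        orientation = "ambiguous"
    return FragmentAssignment(
        qname=rec.qname,
        gene_id=gene.gene_id,
        orientation=orientation,
        unique=unique,
        interval=frag_iv,
    )


@dataclass
class CountMatrix:
    """Features × samples unique-read counts with sample annotations."""

    counts: pd.DataFrame  # rows: feature_ids, columns: sample_ids
    samples: list[SampleMeta]
    stratum: str  # sense_gene | antisense_contig

    def __post_init__(self) -> None:
        sample_ids = [s.sample_id for s in self.samples]
        if list(self.counts.columns) != sample_ids:
            raise ValueError("count matrix columns do not match sample metadata order")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    def sample(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(
        cls, path: str | Path, samples: Sequence[SampleMeta], stratum: str
    ) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
        df.index = df.index.astype(str)
        return cls(counts=df, samples=list(samples), stratum=stratum)


def build_count_matrices(
    assignments_by_sample: Mapping[str, Iterable[FragmentAssignment]],
    samples: Sequence[SampleMeta],
    contigs: Sequence = (),
    gene_ids: Sequence[str] | None = None,
) -> tuple[CountMatrix, CountMatrix]:
    """Build the (sense-by-gene, antisense-by-contig) unique count matrices.

    Only assignments flagged unique are counted.  A fragment counts once
    per feature (mates collapse on qname).  An antisense fragment is
    credited to every cognate contig whose segments it intersects; a
    fragment matching several contigs of one gene is counted for each and
    logged.
    """
    sample_ids = [s.sample_id for s in samples]
    missing = set(assignments_by_sample) - set(sample_ids)
    if missing:
        raise ValueError(f"assignments for unknown samples: {sorted(missing)}")

    contigs_by_gene: dict[str, list] = {}
    for c in contigs:
        contigs_by_gene.setdefault(c.cognate_gene_id, []).append(c)

    genes = set(gene_ids or [])
    sense_counts: dict[str, dict[str, set[str]]] = {}
    anti_counts: dict[str, dict[str, set[str]]] = {}

    for sample_id in sample_ids:
        for a in assignments_by_sample.get(sample_id, ()):
            genes.add(a.gene_id)
            if not a.unique:
                continue
            if a.orientation == "sense":
                sense_counts.setdefault(a.gene_id, {}).setdefault(
                    sample_id, set()
                ).add(a.qname)
            elif a.orientation == "antisense" and a.interval is not None:
                matched = [
                    c
                    for c in contigs_by_gene.get(a.gene_id, [])
                    if any(a.interval.intersects(seg) for seg in c.segments)
                ]
                if len(matched) > 1:
                    logger.info(
                        "fragment %s matches %d contigs of gene %s; counted for each",
                        a.qname, len(matched), a.gene_id,
                    )
                for c in matched:
                    anti_counts.setdefault(c.contig_id, {}).setdefault(
                        sample_id, set()
                    ).add(a.qname)

    gene_index = sorted(genes)
    contig_index = sorted(c.contig_id for c in contigs)

    def _frame(index: list[str], data: dict[str, dict[str, set[str]]]) -> pd.DataFrame:
        df = pd.DataFrame(0, index=index, columns=sample_ids, dtype=int)
        for fid, per_sample in data.items():
            for sid, qnames in per_sample.items():
                df.loc[fid, sid] = len(qnames)
        return df

    sense = CountMatrix(
        counts=_frame(gene_index, sense_counts), samples=list(samples), stratum="sense_gene"
    )
    antisense = CountMatrix(
        counts=_frame(contig_index, anti_counts),
        samples=list(samples),
        stratum="antisense_contig",
    )
    return sense, antisense


def read_sample_sheet(path: str | Path) -> list[tuple[SampleMeta, str]]:
    """Read a sample sheet TSV: sample_id, tissue, age, replicate, sex, sam_path."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "tissue", "age", "replicate", "sex", "sam_path"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample sheet missing columns: {sorted(required - set(df.columns))}")
    out = []
    for row in df.itertuples(index=False):
        age = int(str(row.age).lstrip("P"))
        meta = SampleMeta(
            sample_id=row.sample_id,
            tissue=row.tissue,
            age=age,
            replicate=int(row.replicate),
            sex=row.sex,
        )
        out.append((meta, row.sam_path))
    return out
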