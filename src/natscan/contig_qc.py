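"""De novo antisense contig quality control.

Three filters, applied in order:

1. self-validation against the source genome (identity >= 99%,
   union query coverage >= 95%);
2. unique-read counting (upstream, in :mod:`natscan.strand_reads`);
3. the low-pass spurious filter: keep a contig only when its antisense
   reads exceed 3% of (cognate sense reads + its own antisense reads),
   which removes strand-misassignment artifacts.

Cross-mapping to known lncRNAs uses the stricter coverage reading
(coverage > 95%, identity >= 99%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation import Interval

logger = logging.getLogger(__name__)

__all__ = [
    "BlastHit",
    "ContigRecord",
    "FilterConfig",
    "parse_blast_tab",
    "query_coverage",
    "weighted_identity",
    "self_validate",
    "map_known_lncrna",
    "spurious_filter",
]


@dataclass(frozen=True)
class BlastHit:
    """One HSP row from BLAST tabular output (outfmt 6, plus qlen)."""

    qid: str
    sid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int  # 1-based, qstart <= qend after normalization
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    qlen: int
    subject_reverse: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.pident <= 100.0:
            raise ValueError(f"pident {self.pident} out of [0,100]")
        if self.qstart > self.qend:
            raise ValueError("qstart must be <= qend after normalization")
        if self.qlen <= 0:
            raise ValueError("qlen must be positive")

    @property
    def query_interval(self) -> Interval:
        # query coordinates as a 0-based half-open interval
        return Interval(self.qid, self.qstart - 1, self.qend)


@dataclass
class ContigRecord:
    """A de novo antisense contig and its genomic footprint."""

    contig_id: str
    cognate_gene_id: str
    segments: list[Interval]
    length: int
    antisense_reads: int = 0
    known_lncrna_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"contig {self.contig_id!r}: length must be positive")
        if self.antisense_reads < 0:
            raise ValueError(f"contig {self.contig_id!r}: negative antisense_reads")


@dataclass
class FilterConfig:
    """All filter thresholds in one place.

    Self-validation and lncRNA identity thresholds are inclusive;
    lncRNA coverage and both conservation thresholds are strict.
    """

    self_id_min: float = 99.0
    self_cov_min: float = 95.0
    lnc_id_min: float = 99.0
    lnc_cov_min: float = 95.0
    spurious_frac: float = 0.03
    human_id_min: float = 90.0
    human_cov_min: float = 90.0
    detect_min_reads: int = 10
    detect_min_samples: int = 3
    f_test_alpha: float = 0.05
    spurious_per_sample: bool = False

    def __post_init__(self) -> None:
        for name in ("self_id_min", "self_cov_min", "lnc_id_min", "lnc_cov_min",
                     "human_id_min", "human_cov_min"):
            v = getattr(self, name)
            if not 0.0 < v <= 100.0:
                raise ValueError(f"{name}={v} not in (0,100]")
        if not 0.0 < self.spurious_frac < 1.0:
            raise ValueError("spurious_frac must be in (0,1)")
        if not 0.0 < self.f_test_alpha < 1.0:
            raise ValueError("f_test_alpha must be in (0,1)")


def _read_fasta_lengths(path: str | Path) -> dict[str, int]:
    lengths: dict[str, int] = {}
    name = None
    n = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    lengths[name] = n
                name = line[1:].split()[0]
                n = 0
            elif name is not None:
                n += len(line)
    if name is not None:
        lengths[name] = n
    return lengths


def parse_blast_tab(
    path: str | Path,
    qlen_source: str = "column",
    fasta_path: str | Path | None = None,
) -> dict[str, list[BlastHit]]:
    """Parse BLAST ``-outfmt 6`` (optionally ``6 std qlen``) into hits by query.

    With ``qlen_source="column"`` a 13th qlen column is required; with
    ``"fasta"`` query lengths come from ``fasta_path``.  Subject-reversed
    (minus-strand) hits are retained with ``subject_reverse`` set; query
    coordinates are normalized so qstart <= qend.
    """
    if qlen_source not in ("column", "fasta"):
        raise ValueError(f"unknown qlen_source {qlen_source!r}")
    fasta_lengths: dict[str, int] = {}
    if qlen_source == "fasta":
        if fasta_path is None:
            raise ValueError("qlen_source='fasta' requires fasta_path")
        fasta_lengths = _read_fasta_lengths(fasta_path)

    hits: dict[str, list[BlastHit]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected >=12 columns, got {len(f)}")
            qid, sid = f[0], f[1]
            qstart, qend = int(f[6]), int(f[7])
            sstart, send = int(f[8]), int(f[9])
            if qstart > qend:  # normalize; flip subject to preserve geometry
                qstart, qend = qend, qstart
                sstart, send = send, sstart
            if qlen_source == "column":
                if len(f) < 13:
                    raise ValueError(
                        f"{path}:{lineno}: qlen column missing (qlen_source='column')"
                    )
                qlen = int(f[12])
            else:
                if qid not in fasta_lengths:
                    raise KeyError(f"query {qid!r} absent from FASTA {fasta_path}")
                qlen = fasta_lengths[qid]
            hits.setdefault(qid, []).append(
                BlastHit(
                    qid=qid, sid=sid,
                    pident=float(f[2]), length=int(f[3]),
                    mismatch=int(f[4]), gapopen=int(f[5]),
                    qstart=qstart, qend=qend, sstart=sstart, send=send,
                    evalue=float(f[10]), bitscore=float(f[11]),
                    qlen=qlen, subject_reverse=sstart > send,
                )
            )
    return hits


def query_coverage(hits_for_query: Sequence[BlastHit]) -> float:
    """Percent of the query covered by the union of its HSP spans."""
    if not hits_for_query:
        return 0.0
    qlen = hits_for_query[0].qlen
    spans = sorted((h.qstart - 1, h.qend) for h in hits_for_query)
    covered = 0
    cur_start, cur_end = spans[0]
    for s, e in spans[1:]:
        if s <= cur_end:
            cur_end = max(cur_end, e)
        else:
            covered += cur_end - cur_start
            cur_start, cur_end = s, e
    covered += cur_end - cur_start
    return 100.0 * covered / qlen


def weighted_identity(hits_for_query: Sequence[BlastHit]) -> float:
    """Alignment-length-weighted mean percent identity; 0.0 for no hits."""
    if not hits_for_query:
        logger.debug("weighted_identity on empty hit set -> 0.0")
        return 0.0
    total = sum(h.length for h in hits_for_query)
    return sum(h.pident * h.length for h in hits_for_query) / total


def self_validate(
    contigs: Iterable[ContigRecord],
    hits: Mapping[str, Sequence[BlastHit]],
    cfg: FilterConfig | None = None,
) -> set[str]:
    """Contig ids passing genome self-validation (identity and coverage inclusive)."""
    cfg = cfg or FilterConfig()
    kept: set[str] = set()
    n_no_hits = 0
    for contig in contigs:
        contig_hits = list(hits.get(contig.contig_id, ()))
        if not contig_hits:
            n_no_hits += 1
            continue
        if (
            weighted_identity(contig_hits) >= cfg.self_id_min
            and query_coverage(contig_hits) >= cfg.self_cov_min
        ):
            kept.add(contig.contig_id)
    if n_no_hits:
        logger.info("self_validate: %d contigs had no hits and were removed", n_no_hits)
    return kept


def map_known_lncrna(
    contigs: Iterable[ContigRecord],
    hits_vs_lncrna: Mapping[str, Sequence[BlastHit]],
    cfg: FilterConfig | None = None,
) -> dict[str, set[str]]:
    """Map contigs to known lncRNAs (coverage strictly > threshold, per subject).

    Coverage and identity are evaluated per (contig, lncRNA) subject pair;
    one contig may map to several lncRNAs.
    """
    cfg = cfg or FilterConfig()
    mapping: dict[str, set[str]] = {}
    for contig in contigs:
        by_subject: dict[str, list[BlastHit]] = {}
        for h in hits_vs_lncrna.get(contig.contig_id, ()):
            by_subject.setdefault(h.sid, []).append(h)
        for sid, subject_hits in by_subject.items():
            if (
                query_coverage(subject_hits) > cfg.lnc_cov_min
                and weighted_identity(subject_hits) >= cfg.lnc_id_min
            ):
                mapping.setdefault(contig.contig_id, set()).add(sid)
    return mapping


def spurious_filter(
    contig: ContigRecord,
    gene_sense_reads: int,
    cfg: FilterConfig | None = None,
) -> bool:
    """Low-pass filter: keep iff antisense / (sense + antisense) > spurious_frac.

    Counts are summed unique reads across all samples.  A zero denominator
    removes the contig.
    """
    cfg = cfg or FilterConfig()
    if gene_sense_reads < 0:
        raise ValueError(f"gene {contig.cognate_gene_id!r}: negative sense reads")
    denom = gene_sense_reads + contig.antisense_reads
    if denom == 0:
        return False
    return contig.antisense_reads / denom > cfg.spurious_frac
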