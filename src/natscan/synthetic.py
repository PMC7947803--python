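"""Ground-truth simulator for the antisense analysis.

Generates every input the pipeline consumes — gene annotation with
deliberately overlapping opposite-strand genes, dUTP-protocol stranded
paired-end SAM text (with configurable strand-misassignment and
multi-mapping rates), negative-binomial count matrices over the
2-tissue x 3-age x replicate design, and BLAST-style hit tables with
planted pass/fail subsets — together with a truth record for every
emitted object.

All randomness flows through one :class:`numpy.random.Generator` seeded
from ``SimConfig.seed``; identical configs produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import (
    GeneModel,
    GenomeAnnotation,
    Interval,
    OverlapFreeZone,
    compute_overlap_free_zone,
)
from .contig_qc import BlastHit, ContigRecord
from .strand_reads import CountMatrix, SampleMeta

__all__ = [
    "SimConfig",
    "SimTruth",
    "FragmentTruth",
    "GeneDesign",
    "build_samples",
    "simulate_annotation",
    "simulate_fragments",
    "simulate_count_matrices",
    "simulate_blast_hits",
    "simulate_scenario",
    "write_blast_tab",
]

_CHROM = "chr1"
_SEGMENT_UNIT = 100  # segment lengths are multiples of this => exact % decoys


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_genes: int = 50
    overlap_fraction: float = 0.3
    antisense_fraction: float = 0.6  # genes given a real antisense transcript
    artifact_fraction: float = 0.2  # genes given a misassignment-artifact contig
    tissues: tuple[str, ...] = ("mPFC", "striatum")
    ages: tuple[int, ...] = (7, 14, 56)
    replicates: tuple[int, ...] = (2, 5, 5)
    depth: float = 120.0  # mean sense fragments per gene per sample
    nb_dispersion: float = 0.1
    misassignment_rate: float = 0.03
    multimap_rate: float = 0.0
    antisense_ratio: float = 0.3  # designed antisense:total ratio for real NATs
    mpfc_enrichment: float = 1.0  # antisense fold-enrichment in mPFC
    slope_magnitude: float = 1.2  # |log fold change| P7 -> P56
    fragment_length: int = 150
    read_length: int = 75

    def __post_init__(self) -> None:
        for name in ("overlap_fraction", "antisense_fraction", "artifact_fraction",
                     "misassignment_rate", "multimap_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0 and not (name.endswith("fraction") and v == 1.0):
                raise ValueError(f"{name}={v} out of range")
        if len(self.ages) != len(self.replicates):
            raise ValueError("ages and replicates must have equal length")
        if min(self.replicates) < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class FragmentTruth:
    """Origin of one simulated fragment."""

    qname: str
    sample_id: str
    gene_id: str
    strand: str  # true source-transcript strand
    orientation: str  # sense | antisense (design origin w.r.t. the gene)
    contig_id: str | None
    misassigned: bool
    unique: bool


@dataclass(frozen=True)
class GeneDesign:
    """Per-gene generative design for count simulation."""

    gene_id: str
    baseline_mean: float
    dispersion: float
    mpfc_enrichment: float  # applied to antisense counts in mPFC
    sense_slope_sign: int  # -1, 0, +1
    antisense_slope_sign: int
    antisense_ratio: float  # designed antisense:total ratio (0 => no NAT)
    contig_id: str | None


@dataclass
class SimTruth:
    """Ground truth accumulated across the generators."""

    overlap_partners: dict[str, str] = field(default_factory=dict)
    zones: dict[str, OverlapFreeZone] = field(default_factory=dict)
    contigs: dict[str, ContigRecord] = field(default_factory=dict)
    contig_labels: dict[str, str] = field(default_factory=dict)  # real | artifact
    gene_designs: dict[str, GeneDesign] = field(default_factory=dict)
    fragments: list[FragmentTruth] = field(default_factory=list)
    planted_valid: set[str] = field(default_factory=set)
    planted_conserved: set[str] = field(default_factory=set)
    planted_lncrna: dict[str, set[str]] = field(default_factory=dict)


def build_samples(cfg: SimConfig) -> list[SampleMeta]:
    """The full tissue x age x replicate sample grid, in deterministic order."""
    samples = []
    for tissue in cfg.tissues:
        for age, n_reps in zip(cfg.ages, cfg.replicates):
            for rep in range(1, n_reps + 1):
                samples.append(
                    SampleMeta(
                        sample_id=f"{tissue}_P{age}_r{rep}",
                        tissue=tissue,
                        age=age,
                        replicate=rep,
                        sex="F" if rep % 2 else "M",
                    )
                )
    return samples


# ---------------------------------------------------------------------------
# Annotation


def simulate_annotation(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeAnnotation, SimTruth]:
    """Place genes along one chromosome; a designed fraction receive a fully
    nested opposite-strand partner gene (shrinking their overlap-free zone).

    Genes with a real antisense transcript get a contig of 1-2 segments
    placed inside their overlap-free zone; a further fraction get an
    "artifact" contig fed only by strand-misassigned sense reads.
    """
    if cfg.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    truth = SimTruth()

    genes: list[GeneModel] = []
    cursor = 1000
    n_overlap = int(round(cfg.overlap_fraction * cfg.n_genes))
    overlap_ids = set(range(n_overlap))  # deterministic: first k genes overlap

    for i in range(cfg.n_genes):
        length = int(rng.integers(30, 60)) * _SEGMENT_UNIT  # 3-6 kb
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"gene{i:03d}"
        span = Interval(_CHROM, cursor, cursor + length)
        genes.append(GeneModel(gene_id, _CHROM, strand, span, biotype="protein_coding",
                               exons=[span]))
        if i in overlap_ids:
            # nested opposite-strand partner in the middle third of the span
            blk_len = length // 3 // _SEGMENT_UNIT * _SEGMENT_UNIT or _SEGMENT_UNIT
            blk_start = cursor + length // 3
            partner_id = f"ovl_{gene_id}"
            blk_span = Interval(_CHROM, blk_start, blk_start + blk_len)
            genes.append(
                GeneModel(partner_id, _CHROM, "-" if strand == "+" else "+",
                          blk_span, biotype="lncRNA", exons=[blk_span])
            )
            truth.overlap_partners[gene_id] = partner_id
        cursor += length + int(rng.integers(5, 15)) * _SEGMENT_UNIT

    annotation = GenomeAnnotation(genes)
    primary = [g for g in annotation if not g.gene_id.startswith("ovl_")]
    for g in annotation:
        truth.zones[g.gene_id] = compute_overlap_free_zone(g, annotation)

    # plant contigs: real NATs inside zones, artifacts likewise (they soak up
    # misassigned sense reads only)
    n_real = int(round(cfg.antisense_fraction * len(primary)))
    n_artifact = int(round(cfg.artifact_fraction * len(primary)))
    designees = list(primary)
    rng.shuffle(designees)
    real_genes = designees[:n_real]
    artifact_genes = designees[n_real:n_real + n_artifact]

    def _plant_contig(gene: GeneModel, tag: str, n_segments: int) -> ContigRecord | None:
        zone = truth.zones[gene.gene_id]
        usable = [z for z in zone.zones if len(z) >= 4 * _SEGMENT_UNIT]
        if not usable:
            return None
        z = max(usable, key=len)
        max_units = len(z) // _SEGMENT_UNIT
        segs = []
        offset = z.start
        for k in range(n_segments):
            seg_units = min(3, max_units // n_segments)
            seg_len = seg_units * _SEGMENT_UNIT
            segs.append(Interval(_CHROM, offset, offset + seg_len))
            offset += seg_len + _SEGMENT_UNIT  # intron gap
            if offset >= z.end:
                break
        segs = [s for s in segs if s.end <= z.end]
        if not segs:
            return None
        contig_id = f"{tag}_{gene.gene_id}"
        contig = ContigRecord(
            contig_id=contig_id,
            cognate_gene_id=gene.gene_id,
            segments=segs,
            length=sum(len(s) for s in segs),
        )
        truth.contigs[contig_id] = contig
        truth.contig_labels[contig_id] = "real" if tag == "nat" else "artifact"
        return contig

    for gene in real_genes:
        n_seg = 1 + int(rng.random() < 0.4)
        _plant_contig(gene, "nat", n_seg)
    for gene in artifact_genes:
        _plant_contig(gene, "art", 1)

    # per-gene count design
    for gene in primary:
        contig_id = None
        ratio = 0.0
        for cid, c in truth.contigs.items():
            if c.cognate_gene_id == gene.gene_id and truth.contig_labels[cid] == "real":
                contig_id = cid
                ratio = cfg.antisense_ratio
        sense_sign = int(rng.choice([-1, 1]))
        anti_sign = sense_sign  # default positively correlated, as observed
        truth.gene_designs[gene.gene_id] = GeneDesign(
            gene_id=gene.gene_id,
            baseline_mean=cfg.depth,
            dispersion=cfg.nb_dispersion,
            mpfc_enrichment=cfg.mpfc_enrichment,
            sense_slope_sign=sense_sign,
            antisense_slope_sign=anti_sign,
            antisense_ratio=ratio,
            contig_id=contig_id,
        )
    return annotation, truth


# ---------------------------------------------------------------------------
# Fragments / SAM


def _sam_flags(is_read1: bool, self_reverse: bool, mate_reverse: bool) -> int:
    flag = 0x1 | 0x2  # paired, proper pair
    if self_reverse:
        flag |= 0x10
    if mate_reverse:
        flag |= 0x20
    flag |= 0x40 if is_read1 else 0x80
    return flag


def _emit_pair(
    lines: list[str],
    qname: str,
    seq_id: str,
    frag_start: int,
    frag_end: int,
    transcript_strand: str,
    read_length: int,
    misassigned: bool,
    nh: int,
) -> None:
    """Two SAM records for one fragment under the RF (dUTP) protocol.

    For a '+' transcript, read2 aligns forward at the fragment 5' end and
    read1 reverse at the 3' end; '-' transcripts mirror this.  Strand
    misassignment flips both mates' orientation bits.
    """
    left_pos = frag_start
    right_pos = max(frag_start, frag_end - read_length)
    if transcript_strand == "+":
        r1_pos, r1_rev = right_pos, True
        r2_pos, r2_rev = left_pos, False
    else:
        r1_pos, r1_rev = left_pos, False
        r2_pos, r2_rev = right_pos, True
    if misassigned:
        r1_rev, r2_rev = not r1_rev, not r2_rev
    mapq = 255 if nh == 1 else 3
    cigar = f"{read_length}M"
    tlen = frag_end - frag_start
    for is_read1, pos, rev, mate_rev, sign in (
        (True, r1_pos, r1_rev, r2_rev, -1 if r1_pos >= r2_pos else 1),
        (False, r2_pos, r2_rev, r1_rev, -1 if r2_pos >= r1_pos else 1),
    ):
        mate_pos = r2_pos if is_read1 else r1_pos
        lines.append(
            "\t".join(
                [
                    qname,
                    str(_sam_flags(is_read1, rev, mate_rev)),
                    seq_id,
                    str(pos + 1),
                    str(mapq),
                    cigar,
                    "=",
                    str(mate_pos + 1),
                    str(sign * tlen),
                    "*",
                    "*",
                    f"NH:i:{nh}",
                ]
            )
        )


def _draw_start(rng: np.random.Generator, region: Interval, frag_len: int) -> int:
    hi = max(region.start, region.end - frag_len)
    if hi <= region.start:
        return region.start
    return int(rng.integers(region.start, hi + 1))


def simulate_fragments(
    annotation: GenomeAnnotation,
    truth: SimTruth,
    cfg: SimConfig,
    rng: np.random.Generator,
    sample: SampleMeta,
    mean_scale: dict[str, tuple[float, float]] | None = None,
) -> list[str]:
    """SAM text (list of lines, header included) for one sample.

    ``mean_scale`` maps gene_id to (sense_mean, antisense_mean) for this
    sample; by default flat means from the config are used.  Fragment
    truth entries are appended to ``truth.fragments``.
    """
    chrom_len = max(g.span.end for g in annotation) + 1000
    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        f"@SQ\tSN:{_CHROM}\tLN:{chrom_len}",
        "@PG\tID:natscan-sim\tPN:natscan-sim",
    ]
    frag_len, read_len = cfg.fragment_length, cfg.read_length
    counter = 0
    for gene in sorted(annotation, key=lambda g: g.gene_id):
        if gene.gene_id.startswith("ovl_"):
            continue
        design = truth.gene_designs.get(gene.gene_id)
        if mean_scale and gene.gene_id in mean_scale:
            sense_mean, anti_mean = mean_scale[gene.gene_id]
        else:
            sense_mean = cfg.depth
            ratio = design.antisense_ratio if design else 0.0
            anti_mean = ratio / (1.0 - ratio) * sense_mean if ratio else 0.0

        n_sense = int(rng.poisson(sense_mean))
        anti_strand = "-" if gene.strand == "+" else "+"
        gene_contigs = [
            c for _, c in sorted(truth.contigs.items())
            if c.cognate_gene_id == gene.gene_id
        ]
        real_contigs = [c for c in gene_contigs
                        if truth.contig_labels[c.contig_id] == "real"]

        for _ in range(n_sense):
            counter += 1
            qname = f"{sample.sample_id}:{gene.gene_id}:s{counter}"
            start = _draw_start(rng, gene.span, frag_len)
            end = min(start + frag_len, gene.span.end)
            mis = bool(rng.random() < cfg.misassignment_rate)
            multi = bool(rng.random() < cfg.multimap_rate)
            _emit_pair(lines, qname, gene.seq_id, start, end, gene.strand,
                       read_len, mis, nh=2 if multi else 1)
            truth.fragments.append(
                FragmentTruth(qname, sample.sample_id, gene.gene_id, gene.strand,
                              "sense", None, mis, not multi)
            )

        if real_contigs and anti_mean > 0:
            n_anti = int(rng.poisson(anti_mean))
            for _ in range(n_anti):
                counter += 1
                contig = real_contigs[int(rng.integers(len(real_contigs)))]
                seg = contig.segments[int(rng.integers(len(contig.segments)))]
                qname = f"{sample.sample_id}:{gene.gene_id}:a{counter}"
                start = _draw_start(rng, seg, frag_len)
                end = min(start + frag_len, seg.end)
                mis = bool(rng.random() < cfg.misassignment_rate)
                multi = bool(rng.random() < cfg.multimap_rate)
                _emit_pair(lines, qname, gene.seq_id, start, end, anti_strand,
                           read_len, mis, nh=2 if multi else 1)
                truth.fragments.append(
                    FragmentTruth(qname, sample.sample_id, gene.gene_id, anti_strand,
                                  "antisense", contig.contig_id, mis, not multi)
                )
    return lines


# ---------------------------------------------------------------------------
# Count matrices


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size: int):
    """NB with var = mean + dispersion * mean^2; Poisson in the limit."""
    mean = max(mean, 1e-9)
    if dispersion <= 1e-9:
        return rng.poisson(mean, size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size)


def _design_mean(
    design: GeneDesign, cfg: SimConfig, tissue: str, age: int, antisense: bool
) -> float:
    ages = cfg.ages
    age_frac = (age - ages[0]) / (ages[-1] - ages[0])  # 0 at P7, 1 at P56
    sign = design.antisense_slope_sign if antisense else design.sense_slope_sign
    mean = design.baseline_mean * float(np.exp(cfg.slope_magnitude * sign * (age_frac - 0.5)))
    if antisense:
        r = design.antisense_ratio
        mean *= r / (1.0 - r) if r else 0.0
        if tissue == "mPFC":
            mean *= design.mpfc_enrichment
    return mean


def simulate_count_matrices(
    cfg: SimConfig,
    designs: dict[str, GeneDesign],
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, CountMatrix]:
    """Draw NB sense (by gene) and antisense (by contig) count matrices.

    Per-cell means follow the log-linear age design with tissue enrichment
    applied to antisense counts in mPFC; a designed antisense:total ratio
    ``r`` sets the contig mean to ``r/(1-r)`` times the gene mean so that
    the recovered ratio matches ``r``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    samples = build_samples(cfg)
    gene_ids = sorted(designs)
    contig_rows = [
        (d.contig_id, gid) for gid, d in sorted(designs.items()) if d.contig_id
    ]
    sense = pd.DataFrame(0, index=gene_ids,
                         columns=[s.sample_id for s in samples], dtype=int)
    anti = pd.DataFrame(0, index=[cid for cid, _ in contig_rows],
                        columns=[s.sample_id for s in samples], dtype=int)
    for s in samples:
        for gid in gene_ids:
            d = designs[gid]
            mu = _design_mean(d, cfg, s.tissue, s.age, antisense=False)
            sense.loc[gid, s.sample_id] = _nb_draw(rng, mu, d.dispersion, 1)[0]
        for cid, gid in contig_rows:
            d = designs[gid]
            mu = _design_mean(d, cfg, s.tissue, s.age, antisense=True)
            anti.loc[cid, s.sample_id] = _nb_draw(rng, mu, d.dispersion, 1)[0]
    return (
        CountMatrix(sense, samples, "sense_gene"),
        CountMatrix(anti, samples, "antisense_contig"),
    )


# ---------------------------------------------------------------------------
# BLAST hit tables


def _make_hit(qid: str, sid: str, qstart: int, qend: int, pident: float,
              qlen: int, soffset: int = 10_000) -> BlastHit:
    length = qend - qstart + 1
    return BlastHit(
        qid=qid, sid=sid, pident=round(pident, 2), length=length,
        mismatch=int(round(length * (100.0 - pident) / 100.0)), gapopen=0,
        qstart=qstart, qend=qend,
        sstart=soffset + qstart, send=soffset + qend,
        evalue=1e-30, bitscore=round(2.0 * length, 1), qlen=qlen,
    )


def simulate_blast_hits(
    contigs: Sequence[ContigRecord],
    cfg: SimConfig,
    planted_valid: set[str],
    planted_conserved: set[str],
    rng: np.random.Generator | None = None,
    planted_lncrna: dict[str, set[str]] | None = None,
) -> tuple[dict[str, list[BlastHit]], dict[str, list[BlastHit]], dict[str, list[BlastHit]]]:
    """(self-genome, second-genome, lncRNA) hit tables with planted outcomes.

    Planted-valid contigs get HSP sets with union coverage >= 95% and
    identity >= 99%; planted-conserved get > 90%/> 90% against the second
    genome.  Everything else receives sub-threshold hits or none,
    including exact-boundary decoys (coverage or identity exactly 90.0).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 7)
    unknown = (planted_valid | planted_conserved) - {c.contig_id for c in contigs}
    if unknown:
        raise ValueError(f"planted ids not among contigs: {sorted(unknown)}")
    self_hits: dict[str, list[BlastHit]] = {}
    human_hits: dict[str, list[BlastHit]] = {}
    lnc_hits: dict[str, list[BlastHit]] = {}

    decoy_cycle = 0
    for contig in contigs:
        cid, qlen = contig.contig_id, contig.length

        if cid in planted_valid:
            ident = float(rng.uniform(99.0, 100.0))
            cov_units = int(rng.integers(96, 101))  # 96-100%
            qend = qlen * cov_units // 100
            if rng.random() < 0.5 and qend > 40:
                # split into two overlapping HSPs; union still == [1, qend]
                mid = qend // 2
                self_hits[cid] = [
                    _make_hit(cid, "chr_self", 1, mid + 10, ident, qlen),
                    _make_hit(cid, "chr_self", mid - 10, qend, ident, qlen),
                ]
            else:
                self_hits[cid] = [_make_hit(cid, "chr_self", 1, qend, ident, qlen)]
        else:
            decoy_cycle += 1
            if decoy_cycle % 3 == 0:
                pass  # no hits at all
            elif decoy_cycle % 3 == 1:
                # coverage below 95%
                qend = qlen * int(rng.integers(50, 94)) // 100
                self_hits[cid] = [_make_hit(cid, "chr_self", 1, max(qend, 30),
                                            float(rng.uniform(99.0, 100.0)), qlen)]
            else:
                # identity below 99%
                self_hits[cid] = [_make_hit(cid, "chr_self", 1, qlen,
                                            float(rng.uniform(90.0, 98.9)), qlen)]

        if cid in planted_conserved:
            ident = float(rng.uniform(91.0, 99.5))
            qend = qlen * int(rng.integers(92, 100)) // 100
            human_hits[cid] = [_make_hit(cid, "chr_human", 1, qend, ident, qlen)]
        else:
            decoy_cycle += 1
            if decoy_cycle % 4 == 0:
                human_hits[cid] = [  # coverage exactly 90.0, identity passing
                    _make_hit(cid, "chr_human", 1, qlen * 90 // 100, 95.0, qlen)
                ]
            elif decoy_cycle % 4 == 1:
                human_hits[cid] = [  # identity exactly 90.0, coverage passing
                    _make_hit(cid, "chr_human", 1, qlen * 95 // 100, 90.0, qlen)
                ]
            elif decoy_cycle % 4 == 2:
                human_hits[cid] = [
                    _make_hit(cid, "chr_human", 1, qlen * int(rng.integers(30, 89)) // 100,
                              float(rng.uniform(70.0, 89.9)), qlen)
                ]
            # else: no hits

        for lnc_id in sorted((planted_lncrna or {}).get(cid, ())):
            qend = qlen * int(rng.integers(96, 100)) // 100
            lnc_hits.setdefault(cid, []).append(
                _make_hit(cid, lnc_id, 1, qend, float(rng.uniform(99.0, 100.0)), qlen)
            )
    return self_hits, human_hits, lnc_hits


def write_blast_tab(hits: dict[str, list[BlastHit]], path: str | Path) -> None:
    """Write hits as outfmt '6 std qlen' (13 columns)."""
    with open(path, "w") as fh:
        for qid in sorted(hits):
            for h in hits[qid]:
                sstart, send = (h.send, h.sstart) if h.subject_reverse else (h.sstart, h.send)
                fh.write(
                    "\t".join(
                        str(x)
                        for x in [
                            h.qid, h.sid, h.pident, h.length, h.mismatch, h.gapopen,
                            h.qstart, h.qend, sstart, send, h.evalue, h.bitscore, h.qlen,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Full scenario


def _write_annotation_gtf(annotation: GenomeAnnotation, path: Path) -> None:
    lines = []
    for g in sorted(annotation, key=lambda g: g.gene_id):
        attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
        lines.append("\t".join([
            g.seq_id, "natscan-sim", "gene",
            str(g.span.start + 1), str(g.span.end), ".", g.strand, ".", attrs,
        ]))
        for ex in g.exons:
            lines.append("\t".join([
                ex.seq_id, "natscan-sim", "exon",
                str(ex.start + 1), str(ex.end), ".", g.strand, ".",
                attrs + f' transcript_id "{g.gene_id}.t1";',
            ]))
    path.write_text("\n".join(lines) + "\n")


def _write_contig_table(truth: SimTruth, path: Path) -> None:
    rows = []
    for cid in sorted(truth.contigs):
        c = truth.contigs[cid]
        segs = ";".join(f"{s.seq_id}:{s.start}-{s.end}" for s in c.segments)
        rows.append({
            "contig_id": cid,
            "cognate_gene_id": c.cognate_gene_id,
            "segments": segs,
            "length": c.length,
            "label": truth.contig_labels[cid],
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def simulate_scenario(cfg: SimConfig, out_dir: str | Path) -> SimTruth:
    """Generate the full input set for a pipeline run under ``out_dir``.

    Writes: annotation.gtf, contigs.tsv, sample_sheet.tsv, one SAM per
    sample, blast_self.tsv / blast_human.tsv / blast_lncrna.tsv,
    gene_list.txt, and truth tables (truth_fragments.tsv,
    truth_designs.tsv).  Fully deterministic for a fixed config.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    annotation, truth = simulate_annotation(cfg, rng)
    _write_annotation_gtf(annotation, out_dir / "annotation.gtf")
    _write_contig_table(truth, out_dir / "contigs.tsv")

    samples = build_samples(cfg)
    sheet_rows = []
    for s in samples:
        sam_path = out_dir / f"{s.sample_id}.sam"
        per_gene = {
            gid: (
                _design_mean(d, cfg, s.tissue, s.age, antisense=False),
                _design_mean(d, cfg, s.tissue, s.age, antisense=True),
            )
            for gid, d in truth.gene_designs.items()
        }
        lines = simulate_fragments(annotation, truth, cfg, rng, s, mean_scale=per_gene)
        sam_path.write_text("\n".join(lines) + "\n")
        sheet_rows.append({
            "sample_id": s.sample_id, "tissue": s.tissue, "age": f"P{s.age}",
            "replicate": s.replicate, "sex": s.sex, "sam_path": str(sam_path),
        })
    pd.DataFrame(sheet_rows).to_csv(out_dir / "sample_sheet.tsv", sep="\t", index=False)

    contigs = [truth.contigs[cid] for cid in sorted(truth.contigs)]
    # every planted contig is genuinely genomic => BLAST-valid; conserve a
    # deterministic half of the real NATs
    truth.planted_valid = set(truth.contigs)
    real_ids = sorted(cid for cid, lab in truth.contig_labels.items() if lab == "real")
    truth.planted_conserved = set(real_ids[::2])
    truth.planted_lncrna = {cid: {f"lnc_{cid}"} for cid in real_ids[::3]}
    self_hits, human_hits, lnc_hits = simulate_blast_hits(
        contigs, cfg, truth.planted_valid, truth.planted_conserved,
        np.random.default_rng(cfg.seed + 7), truth.planted_lncrna,
    )
    write_blast_tab(self_hits, out_dir / "blast_self.tsv")
    write_blast_tab(human_hits, out_dir / "blast_human.tsv")
    write_blast_tab(lnc_hits, out_dir / "blast_lncrna.tsv")

    gene_list = sorted(truth.gene_designs)[: max(5, cfg.n_genes // 2)]
    (out_dir / "gene_list.txt").write_text("\n".join(gene_list) + "\n")

    pd.DataFrame([vars(f) for f in truth.fragments]).to_csv(
        out_dir / "truth_fragments.tsv", sep="\t", index=False
    )
    pd.DataFrame([vars(d) for d in truth.gene_designs.values()]).to_csv(
        out_dir / "truth_designs.tsv", sep="\t", index=False
    )
    return truth
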