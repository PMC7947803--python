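"""End-to-end orchestration: extract -> qc -> expression -> devcorr -> conserve.

Every stage writes a TSV report under the output directory; the run is
summarized in a machine-readable ``run_report.json``.  Outputs are fully
deterministic for a fixed config (sorted orderings, no timestamps).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .annotation import GenomeAnnotation, Interval, OverlapFreeZone, compute_overlap_free_zone, load_annotation
from .contig_qc import (
    ContigRecord,
    FilterConfig,
    map_known_lncrna,
    parse_blast_tab,
    self_validate,
    spurious_filter,
)
from .conservation import conservation_filter, cross_reference_genes, read_gene_list
from .devcorr import classify_pair, fit_linear_model, summarize_quadrants
from .expression import (
    TissueReadSummary,
    antisense_total_ratio,
    combined_library_sizes,
    detection_filter,
    normalize_library_size,
    tss_report,
)
from .strand_reads import (
    CountMatrix,
    build_count_matrices,
    classify_fragment,
    parse_sam,
    read_sample_sheet,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "load_contig_table"]


@dataclass
class PipelineConfig:
    annotation: str
    sample_sheet: str
    contigs: str
    blast_self: str
    blast_human: str
    gene_list: str
    out_dir: str
    blast_lncrna: str | None = None
    protocol: str = "RF"
    min_mapq: int = 30
    seed: int = 0
    filters: FilterConfig = field(default_factory=FilterConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        filt = FilterConfig(**raw.pop("filters", {}))
        return cls(filters=filt, **raw)

    def validate(self) -> None:
        for name in ("annotation", "sample_sheet", "contigs", "blast_self",
                     "blast_human", "gene_list"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"config path {name!r} does not exist: {p}")
        if self.blast_lncrna and not Path(self.blast_lncrna).exists():
            raise FileNotFoundError(f"blast_lncrna does not exist: {self.blast_lncrna}")


@dataclass
class RunReport:
    version: str
    config: dict
    counts: dict  # per-stage counters, monotone through the filter cascade

    def to_json(self, path: str | Path) -> None:
        payload = {"version": self.version, "config": self.config, "counts": self.counts}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_contig_table(path: str | Path) -> list[ContigRecord]:
    """Contig table TSV: contig_id, cognate_gene_id, segments, length.

    Segments are ';'-joined ``seq:start-end`` tokens in 0-based half-open
    coordinates.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    contigs = []
    for row in df.itertuples(index=False):
        segments = []
        for token in str(row.segments).split(";"):
            seq, _, span = token.partition(":")
            start_s, _, end_s = span.partition("-")
            segments.append(Interval(seq, int(start_s), int(end_s)))
        contigs.append(
            ContigRecord(
                contig_id=row.contig_id,
                cognate_gene_id=row.cognate_gene_id,
                segments=segments,
                length=int(row.length),
            )
        )
    return contigs


def extract_assignments(
    sam_path: str | Path,
    annotation: GenomeAnnotation,
    zones: Mapping[str, OverlapFreeZone],
    protocol: str = "RF",
    min_mapq: int = 30,
):
    """Classify every mapped primary record against every gene it overlaps."""
    assignments = []
    for rec in parse_sam(sam_path):
        for gene in annotation.overlapping(rec.interval):
            assignments.append(
                classify_fragment(rec, gene, zones[gene.gene_id], protocol, min_mapq)
            )
    return assignments


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    removal_reasons: dict[str, str] = {}

    # --- load inputs -------------------------------------------------------
    annotation = load_annotation(cfg.annotation)
    contigs = load_contig_table(cfg.contigs)
    contig_by_id = {c.contig_id: c for c in contigs}
    samples_and_paths = read_sample_sheet(cfg.sample_sheet)
    samples = [meta for meta, _ in samples_and_paths]
    gene_list = read_gene_list(cfg.gene_list)
    counts["genes_annotated"] = len(annotation)
    counts["contigs_input"] = len(contigs)
    counts["samples"] = len(samples)

    zones = {g.gene_id: compute_overlap_free_zone(g, annotation) for g in annotation}

    # --- stage qc 1: genome self-validation --------------------------------
    self_hits = parse_blast_tab(cfg.blast_self, qlen_source="column")
    kept_ids = self_validate(contigs, self_hits, cfg.filters)
    for c in contigs:
        if c.contig_id not in kept_ids:
            removal_reasons[c.contig_id] = "self_validation"
    kept_contigs = [c for c in contigs if c.contig_id in kept_ids]
    counts["contigs_self_validated"] = len(kept_contigs)

    # --- stage extract: classify fragments, build matrices -----------------
    assignments_by_sample = {}
    for meta, sam_path in samples_and_paths:
        assignments_by_sample[meta.sample_id] = extract_assignments(
            sam_path, annotation, zones, cfg.protocol, cfg.min_mapq
        )
    sense_m, anti_m = build_count_matrices(
        assignments_by_sample, samples, kept_contigs, gene_ids=annotation.gene_ids
    )
    sense_m.to_tsv(out_dir / "counts_sense.tsv")
    anti_m.to_tsv(out_dir / "counts_antisense.tsv")
    counts["fragments_sense"] = int(sense_m.counts.to_numpy().sum())
    counts["fragments_antisense"] = int(anti_m.counts.to_numpy().sum())

    # --- stage qc 2: spurious low-pass filter ------------------------------
    sense_totals = sense_m.counts.sum(axis=1)
    anti_totals = anti_m.counts.sum(axis=1)
    surviving = []
    for c in kept_contigs:
        c.antisense_reads = int(anti_totals.get(c.contig_id, 0))
        gene_reads = int(sense_totals.get(c.cognate_gene_id, 0))
        if spurious_filter(c, gene_reads, cfg.filters):
            surviving.append(c)
        else:
            removal_reasons[c.contig_id] = "spurious_low_pass"
    counts["contigs_after_spurious_filter"] = len(surviving)
    surviving_ids = {c.contig_id for c in surviving}

    # optional lncRNA cross-mapping
    if cfg.blast_lncrna:
        lnc_hits = parse_blast_tab(cfg.blast_lncrna, qlen_source="column")
        lnc_map = map_known_lncrna(surviving, lnc_hits, cfg.filters)
        for c in surviving:
            c.known_lncrna_ids = lnc_map.get(c.contig_id, set())
        counts["contigs_mapped_to_lncrna"] = len(lnc_map)
        counts["lncrnas_hit"] = len(set().union(*lnc_map.values())) if lnc_map else 0

    pd.DataFrame(
        [
            {"contig_id": cid, "removal_reason": removal_reasons[cid]}
            for cid in sorted(removal_reasons)
        ],
        columns=["contig_id", "removal_reason"],
    ).to_csv(out_dir / "removed_contigs.tsv", sep="\t", index=False)

    # --- stage expression --------------------------------------------------
    lib_sizes = combined_library_sizes(sense_m, anti_m)
    sense_norm = normalize_library_size(sense_m, lib_sizes)
    anti_norm = normalize_library_size(anti_m, lib_sizes)

    detected_genes = detection_filter(sense_m, cfg.filters)
    detected_contigs = detection_filter(anti_m, cfg.filters) & surviving_ids
    counts["genes_detected"] = len(detected_genes)
    counts["contigs_detected"] = len(detected_contigs)

    contig_map: dict[str, list[str]] = {}
    for c in surviving:
        contig_map.setdefault(c.cognate_gene_id, []).append(c.contig_id)

    ratios = [
        antisense_total_ratio(gid, sense_norm, anti_norm, contig_map)
        for gid in sorted(sense_norm.index)
    ]
    pd.DataFrame(
        [
            {"gene_id": r.gene_id, "sense_sum": round(r.sense_sum, 4),
             "antisense_sum": round(r.antisense_sum, 4), "ratio": round(r.ratio, 6)}
            for r in ratios
        ]
    ).to_csv(out_dir / "antisense_ratio.tsv", sep="\t", index=False)

    # TSS over genes with >=1 surviving cognate contig
    tissue_of = {s.sample_id: s.tissue for s in samples}
    mpfc_cols = [sid for sid, t in tissue_of.items() if t == "mPFC"]
    str_cols = [sid for sid, t in tissue_of.items() if t != "mPFC"]
    summaries = {}
    for gid in sorted(contig_map):
        if gid not in sense_norm.index:
            continue
        cids = [c for c in contig_map[gid] if c in anti_norm.index]
        opp_mpfc = float(anti_norm.loc[cids, mpfc_cols].to_numpy().sum())
        opp_str = float(anti_norm.loc[cids, str_cols].to_numpy().sum())
        sense_mpfc = float(sense_norm.loc[gid, mpfc_cols].sum())
        sense_str = float(sense_norm.loc[gid, str_cols].sum())
        summaries[gid] = TissueReadSummary(
            mpfc_opp_reads=opp_mpfc, mpfc_total=sense_mpfc + opp_mpfc,
            str_opp_reads=opp_str, str_total=sense_str + opp_str,
        )
    tss_df = tss_report(summaries)
    tss_df.round(6).to_csv(out_dir / "tss_report.tsv", sep="\t", index=False)
    counts["genes_with_tss"] = int(tss_df["TSS"].notna().sum())

    # --- stage devcorr -----------------------------------------------------
    ages = {s.sample_id: s.age for s in samples}
    alpha = cfg.filters.f_test_alpha
    pair_rows = []
    classifications = []
    for tissue in sorted({s.tissue for s in samples}):
        cols = [s.sample_id for s in samples if s.tissue == tissue]
        col_ages = [ages[c] for c in cols]
        for gid in sorted(contig_map):
            if gid not in detected_genes or gid not in sense_norm.index:
                continue
            gene_fit = fit_linear_model(
                sense_norm.loc[gid, cols].to_numpy(), col_ages, alpha,
                feature_id=gid, tissue=tissue,
            )
            for cid in contig_map[gid]:
                if cid not in detected_contigs:
                    continue
                contig_fit = fit_linear_model(
                    anti_norm.loc[cid, cols].to_numpy(), col_ages, alpha,
                    feature_id=cid, tissue=tissue,
                )
                pc = classify_pair(gene_fit, contig_fit)
                classifications.append(pc)
                pair_rows.append({
                    "gene_id": gid, "contig_id": cid, "tissue": tissue,
                    "gene_slope": round(gene_fit.slope, 6),
                    "contig_slope": round(contig_fit.slope, 6),
                    "gene_p": round(gene_fit.f_pvalue, 8),
                    "contig_p": round(contig_fit.f_pvalue, 8),
                    "gene_fallback": gene_fit.used_fallback,
                    "contig_fallback": contig_fit.used_fallback,
                    "class": pc.klass,
                })
    pd.DataFrame(
        pair_rows,
        columns=["gene_id", "contig_id", "tissue", "gene_slope", "contig_slope",
                 "gene_p", "contig_p", "gene_fallback", "contig_fallback", "class"],
    ).to_csv(out_dir / "pair_classification.tsv", sep="\t", index=False)
    quad = summarize_quadrants(classifications)
    quad.to_csv(out_dir / "quadrant_summary.tsv", sep="\t")
    counts["pairs_classified"] = len(classifications)
    counts["pairs_by_class"] = {
        t: {k: int(v) for k, v in row.items()} for t, row in quad.iterrows()
    }

    # --- stage conservation ------------------------------------------------
    human_hits = parse_blast_tab(cfg.blast_human, qlen_source="column")
    calls = conservation_filter(surviving, human_hits, cfg.filters)
    pd.DataFrame(
        [
            {"contig_id": c.contig_id, "cognate_gene_id": c.cognate_gene_id,
             "coverage": round(c.best_coverage, 4), "identity": round(c.best_identity, 4),
             "conserved": c.conserved}
            for c in sorted(calls, key=lambda c: c.contig_id)
        ]
    ).to_csv(out_dir / "conservation_calls.tsv", sep="\t", index=False)
    xref = cross_reference_genes(calls, gene_list, known_genes=set(annotation.gene_ids))
    xref.to_csv(out_dir / "gene_list_conservation.tsv", sep="\t", index=False)
    counts["contigs_conserved"] = sum(c.conserved for c in calls)
    counts["listed_genes_with_antisense"] = int((xref["n_contigs"] > 0).sum())
    counts["listed_genes_with_conserved_antisense"] = int((xref["n_conserved"] > 0).sum())

    report = RunReport(
        version=__version__,
        config={
            "protocol": cfg.protocol, "min_mapq": cfg.min_mapq, "seed": cfg.seed,
            "filters": vars(cfg.filters),
        },
        counts=counts,
    )
    report.to_json(out_dir / "run_report.json")
    return report
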