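"""Cross-species conservation filtering of antisense contigs.

A contig is called conserved when its hits against the second genome give
union query coverage > 90% AND length-weighted identity > 90% (both
strict).  Conserved calls are then cross-referenced against a gene list
of interest (e.g., ASD-related genes, already mapped to this genome's
symbols).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .contig_qc import BlastHit, ContigRecord, FilterConfig, query_coverage, weighted_identity

__all__ = ["ConservationCall", "conservation_filter", "cross_reference_genes", "read_gene_list"]


@dataclass(frozen=True)
class ConservationCall:
    contig_id: str
    cognate_gene_id: str
    best_coverage: float
    best_identity: float
    conserved: bool


def conservation_filter(
    contigs: Iterable[ContigRecord],
    hits_vs_second_genome: Mapping[str, Sequence[BlastHit]],
    cfg: FilterConfig | None = None,
) -> list[ConservationCall]:
    """Call conservation per contig; both thresholds strictly exceeded.

    Contigs with no hits get coverage 0 and are not conserved.
    """
    cfg = cfg or FilterConfig()
    calls = []
    for contig in contigs:
        contig_hits = list(hits_vs_second_genome.get(contig.contig_id, ()))
        cov = query_coverage(contig_hits)
        ident = weighted_identity(contig_hits)
        calls.append(
            ConservationCall(
                contig_id=contig.contig_id,
                cognate_gene_id=contig.cognate_gene_id,
                best_coverage=cov,
                best_identity=ident,
                conserved=cov > cfg.human_cov_min and ident > cfg.human_id_min,
            )
        )
    return calls


def cross_reference_genes(
    calls: Iterable[ConservationCall],
    gene_list: Sequence[str],
    known_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Per-gene table of cognate and conserved contigs for a gene list.

    One row per listed gene: number of cognate contigs, number conserved,
    comma-joined conserved contig ids, and a flag for genes absent from
    the annotation (when ``known_genes`` is supplied).
    """
    if not gene_list:
        raise ValueError("gene list is empty")
    by_gene: dict[str, list[ConservationCall]] = {}
    for c in calls:
        by_gene.setdefault(c.cognate_gene_id, []).append(c)
    rows = []
    for gene_id in gene_list:
        gene_calls = by_gene.get(gene_id, [])
        conserved = sorted(c.contig_id for c in gene_calls if c.conserved)
        rows.append(
            {
                "gene_id": gene_id,
                "n_contigs": len(gene_calls),
                "n_conserved": len(conserved),
                "conserved_contigs": ",".join(conserved),
                "in_annotation": known_genes is None or gene_id in known_genes,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "n_contigs", "n_conserved", "conserved_contigs", "in_annotation"],
    )


def read_gene_list(path) -> list[str]:
    """Plain-text gene list, one symbol per line; blanks and '#' comments skipped."""
    genes = []
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                genes.append(sym)
    return genes
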