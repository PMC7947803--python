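"""Expression summaries: CPM normalization, the detection filter,
antisense:total ratios, and the tissue specificity score (TSS).

TSS contrasts a gene's antisense read proportion between the two brain
regions, normalized by the pooled antisense proportion::

    TSS = 100 * [ Opp_mPFC/Total_mPFC - Opp_Str/Total_Str ]
              / [ (Opp_mPFC + Opp_Str) / (Total_mPFC + Total_Str) ]

Positive scores indicate mPFC enrichment of antisense reads, negative
scores striatum enrichment.  Inputs are library-size-normalized counts
summed over all samples of each tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contig_qc import FilterConfig
from .strand_reads import CountMatrix

__all__ = [
    "TissueReadSummary",
    "GeneExpressionSummary",
    "UndefinedScoreError",
    "normalize_library_size",
    "combined_library_sizes",
    "detection_filter",
    "antisense_total_ratio",
    "tissue_specificity_score",
    "tss_report",
]


class UndefinedScoreError(ValueError):
    """Raised when the TSS preconditions do not hold for a gene."""


@dataclass(frozen=True)
class TissueReadSummary:
    """Per-gene normalized read totals by tissue and strand."""

    mpfc_opp_reads: float
    mpfc_total: float
    str_opp_reads: float
    str_total: float

    def __post_init__(self) -> None:
        if not 0 <= self.mpfc_opp_reads <= self.mpfc_total:
            raise ValueError("mPFC Opp_Reads must lie in [0, mPFC Total]")
        if not 0 <= self.str_opp_reads <= self.str_total:
            raise ValueError("Str Opp_Reads must lie in [0, Str Total]")

    @property
    def total_reads(self) -> float:
        return self.mpfc_total + self.str_total


@dataclass(frozen=True)
class GeneExpressionSummary:
    gene_id: str
    sense_sum: float
    antisense_sum: float
    ratio: float  # antisense / (sense + antisense); 0 when denominator is 0
    denominator_zero: bool = False


def combined_library_sizes(*matrices: CountMatrix) -> pd.Series:
    """Per-sample library sizes summed across strata (sense + antisense)."""
    if not matrices:
        raise ValueError("at least one matrix required")
    total = None
    for m in matrices:
        col_sums = m.counts.sum(axis=0)
        total = col_sums if total is None else total.add(col_sums, fill_value=0)
    return total


def normalize_library_size(
    m: CountMatrix, library_sizes: pd.Series | None = None
) -> pd.DataFrame:
    """Scale counts to counts-per-million per sample.

    ``library_sizes`` should be the combined sense+antisense totals per
    sample; when omitted, the matrix's own column sums are used.
    """
    sizes = library_sizes if library_sizes is not None else m.counts.sum(axis=0)
    zero = sizes[sizes <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return m.counts.div(sizes, axis=1) * 1e6


def detection_filter(m: CountMatrix, cfg: FilterConfig | None = None) -> set[str]:
    """Features with >= detect_min_reads raw counts in >= detect_min_samples samples."""
    cfg = cfg or FilterConfig()
    qualifying = (m.counts >= cfg.detect_min_reads).sum(axis=1)
    return set(m.counts.index[qualifying >= cfg.detect_min_samples])


def antisense_total_ratio(
    gene_id: str,
    sense_norm: pd.DataFrame,
    antisense_norm: pd.DataFrame,
    contig_map: Mapping[str, Sequence[str]],
) -> GeneExpressionSummary:
    """Summed antisense abundance of a gene's cognate contigs over its total.

    Sums normalized counts over all samples for the gene and for every
    cognate contig; ratio = antisense / (sense + antisense).
    """
    if gene_id not in sense_norm.index:
        raise KeyError(f"gene {gene_id!r} not in sense matrix")
    sense_sum = float(sense_norm.loc[gene_id].sum())
    contig_ids = [c for c in contig_map.get(gene_id, ()) if c in antisense_norm.index]
    antisense_sum = float(antisense_norm.loc[contig_ids].to_numpy().sum()) if contig_ids else 0.0
    denom = sense_sum + antisense_sum
    if denom == 0:
        return GeneExpressionSummary(gene_id, 0.0, 0.0, 0.0, denominator_zero=True)
    return GeneExpressionSummary(gene_id, sense_sum, antisense_sum, antisense_sum / denom)


def tissue_specificity_score(s: TissueReadSummary) -> float:
    """Evaluate the TSS for one gene; positive means mPFC enrichment.

    Raises :class:`UndefinedScoreError` when either tissue total is zero or
    there are no antisense reads at all (the score is undefined and the
    gene is excluded from the report).
    """
    if s.mpfc_total <= 0 or s.str_total <= 0:
        raise UndefinedScoreError("TSS undefined: zero total reads in a tissue")
    opp_pooled = s.mpfc_opp_reads + s.str_opp_reads
    if opp_pooled <= 0:
        raise UndefinedScoreError("TSS undefined: no antisense reads in either tissue")
    numerator = s.mpfc_opp_reads / s.mpfc_total - s.str_opp_reads / s.str_total
    denominator = opp_pooled / s.total_reads
    return 100.0 * numerator / denominator


def tss_report(
    summaries: Mapping[str, TissueReadSummary],
) -> pd.DataFrame:
    """TSS table over genes; undefined scores are flagged and left as NaN."""
    rows = []
    for gene_id in sorted(summaries):
        s = summaries[gene_id]
        try:
            score: float = tissue_specificity_score(s)
            flag = ""
        except UndefinedScoreError as exc:
            score, flag = np.nan, str(exc)
        rows.append(
            {
                "gene_id": gene_id,
                "mPFC_OppReads": s.mpfc_opp_reads,
                "mPFC_Total": s.mpfc_total,
                "Str_OppReads": s.str_opp_reads,
                "Str_Total": s.str_total,
                "TSS": score,
                "flags": flag,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "mPFC_OppReads", "mPFC_Total",
            "Str_OppReads", "Str_Total", "TSS", "flags",
        ],
    )
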