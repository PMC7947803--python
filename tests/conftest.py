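import numpy as np
import pytest

from natscan.annotation import GeneModel, GenomeAnnotation, Interval


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_gene(gene_id, start, end, strand="+", seq_id="chr1", biotype="protein_coding"):
    span = Interval(seq_id, start, end)
    return GeneModel(gene_id, seq_id, strand, span, biotype=biotype, exons=[span])


@pytest.fixture
def two_gene_annotation():
    """Gene X + strand [100,1000) overlapped by gene Y - strand [400,600)."""
    return GenomeAnnotation(
        [make_gene("X", 100, 1000, "+"), make_gene("Y", 400, 600, "-")]
    )


def random_annotation(rng, n_genes=None, max_coord=10_000):
    """Small random annotation for oracle comparisons (<=10 genes, <10 kb)."""
    n = n_genes if n_genes is not None else int(rng.integers(1, 11))
    genes = []
    for i in range(n):
        start = int(rng.integers(0, max_coord - 100))
        length = int(rng.integers(50, min(3000, max_coord - start)))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(make_gene(f"g{i}", start, start + length, strand))
    return GenomeAnnotation(genes)


def brute_force_zone_mask(gene, annotation):
    """Per-base oracle: base kept iff inside the gene span and inside no
    opposite-strand other gene."""
    keep = []
    for pos in range(gene.span.start, gene.span.end):
        blocked = any(
            other.gene_id != gene.gene_id
            and other.strand != gene.strand
            and other.seq_id == gene.seq_id
            and other.span.contains_point(pos)
            for other in annotation
        )
        if not blocked:
            keep.append(pos)
    return keep


def zones_to_mask(zone):
    out = []
    for iv in zone.zones:
        out.extend(range(iv.start, iv.end))
    return out
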