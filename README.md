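# natscan

Strand-aware identification and characterization of natural antisense
transcripts (NATs) from stranded RNA-seq, exercisable end-to-end on
synthetic data with known ground truth.

The pipeline covers:

- **annotation** — GTF loading, UTR-inclusive gene spans, and per-gene
  *overlap-free zones* (the gene span minus every opposite-strand gene),
  the only region where antisense reads are unambiguously attributable.
- **strand_reads** — SAM-text parsing, fragment strand inference under the
  dUTP (`RF`) or `FR` protocol, per-gene sense/antisense classification
  restricted to overlap-free zones, and unique-read count matrices
  (NH tag authoritative, MAPQ fallback; mates deduplicated by qname).
- **contig_qc** — validation of de novo antisense contigs: BLAST outfmt-6
  parsing, union query coverage and length-weighted identity,
  genome self-validation (identity ≥ 99%, coverage ≥ 95%), known-lncRNA
  cross-mapping (coverage > 95%, identity ≥ 99%), and the 3% low-pass
  filter removing strand-misassignment artifacts
  (keep iff antisense/(sense+antisense) > 0.03, strict).
- **expression** — CPM normalization over combined sense+antisense library
  sizes, the ≥10-reads-in-≥3-samples detection filter, antisense:total
  ratios, and the tissue specificity score (TSS) contrasting antisense
  proportions between mPFC and striatum.
- **devcorr** — per-feature OLS of expression on age (P7/P14/P56) with the
  model F-test and a P14+P56 fallback fit, plus slope-sign classification
  of sense–antisense pairs (positive / negative / flat / unfit).
- **conservation** — cross-species similarity filter (> 90% coverage and
  > 90% identity, strict) and gene-list cross-referencing.
- **synthetic** — a fully deterministic simulator for all of the above:
  annotations with planted opposite-strand overlaps, stranded paired-end
  SAM text with configurable strand-misassignment and multi-mapping
  rates, negative-binomial count matrices over the
  2-tissue × 3-age × replicate design, and BLAST hit tables with planted
  pass/fail subsets including exact-boundary decoys.

## CLI

```sh
# generate a synthetic dataset with ground truth
natscan simulate --seed 1 --out sim/

# full pipeline from a YAML config
natscan run --config cfg.yaml

# single stages
natscan zones --annotation sim/annotation.gtf --out zones.tsv
natscan qc --contigs sim/contigs.tsv --blast-self sim/blast_self.tsv --out qc.tsv
natscan conserve --contigs sim/contigs.tsv --blast-human sim/blast_human.tsv \
    --gene-list sim/gene_list.txt --out conservation.tsv
```

A pipeline config lists input paths and optional filter overrides:

```yaml
annotation: sim/annotation.gtf
sample_sheet: sim/sample_sheet.tsv
contigs: sim/contigs.tsv
blast_self: sim/blast_self.tsv
blast_human: sim/blast_human.tsv
blast_lncrna: sim/blast_lncrna.tsv   # optional
gene_list: sim/gene_list.txt
out_dir: out/
filters:
  spurious_frac: 0.03
```

Outputs under `out_dir`: count matrices, removed-contig reasons, the
antisense-ratio and TSS tables, pair classifications with quadrant
summary, conservation calls, and a machine-readable `run_report.json`.
Runs are byte-for-byte deterministic for a fixed config.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
comparisons, boundary behavior, statistical calibration, end-to-end truth
recovery, determinism), one test per criterion.

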