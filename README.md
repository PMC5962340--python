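# charkit

Toolkit for mapping RNA-to-DNA contacts from chimeric proximity-ligation
reads. Each sequencing read carries an RNA-derived fragment and a genomic
DNA fragment joined by a bridge adapter whose polarity distinguishes the two
sides. charkit implements the full computational path:

1. **bridge** — exact-sequence read deduplication, bridge localization
   (substitution-only Hamming matching, both orientations), and splitting
   into RNA-side and DNA-side sequences. Reads lacking a full bridge or
   containing more than one are dropped.
2. **annotation** — sense-first annotation of the RNA side against ranked
   transcript category references (tRNA > miscRNA > ncRNA > transcript >
   3'UTR > 5'UTR > exon > intron > miRNA > gene > gene_extended2000, with
   tRNA/miscRNA removed), and unique-placement filtering of the DNA side.
   A bundled exact-match aligner (`ToyAligner`) stands in for an external
   aligner at desk scale; SAM input is supported via `charkit.io.read_sam`.
3. **contacts** — rejoining both sides by read ID into RNA-DNA contacts,
   rRNA removal, and blacklist/repeat filtering with full loss accounting.
4. **tracks** — binned coverage normalized by GATC (DpnII) restriction-site
   density (bins without a site are excluded, not zeroed), optional chrX
   count doubling for male cells, observed/expected log2 z-score tracks,
   region metaprofiles, and the +4/−5 ATAC insertion-site shift.
5. **stats** — CPKM tables and expression fold-enrichment selection,
   one-tailed binomial chromosome enrichment (extended-precision tail),
   top-bin signal-to-noise versus random autosomal bins, cross-track
   Spearman resolution curves, the TAD boundary-versus-midpoint test with
   masked-length-matched subsampling, and the spike-in false-positive
   estimator with Clopper–Pearson intervals.
6. **simulate** — a fully seeded synthetic-data generator: toy genome with
   planted GATC sites, annotated transcripts in three localization classes
   (cis-local, genome-wide, X-coating with a planted fold), TADs, spike-in
   transcripts, and chimeric reads with configurable noise (bridge-less,
   multi-bridge, PCR duplicates, substitution errors, antisense fraction,
   spike leak), each with a ground-truth record.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` contains the release criteria (oracle
equivalence, end-to-end truth recovery at 100k reads, statistical
calibration and power on planted simulations); the rest are per-module unit
and property tests.

## CLI

```sh
charkit simulate --seed 1 --out simdata/            # synthetic dataset + truth
charkit split --fastq reads.fastq --bridge bridge.yaml --out-prefix sample
charkit annotate --rna-fastq sample.rna.fastq --refs-dir simdata/references --out ann.tsv
charkit contacts --rna ann.tsv --dna-fastq sample.dna.fastq \
    --genome simdata/genome.fa --out-prefix sample
charkit track --contacts sample.contacts.tsv --genome simdata/genome.fa \
    --bin 200 --normalize dpnii --out cov.bedgraph
charkit enrich --contacts sample.contacts.tsv --genome simdata/genome.fa \
    --chrom chrX --out enrich.json
charkit run --seed 1 --out rundir/                  # simulate + full pipeline
```

Other subcommands: `toyalign`, `cpkm`, `snr`, `resolution`, `tadtest`.
The bridge spec is always a config input, e.g.

```yaml
# bridge.yaml
sequence: AACCGGTTCAGCTTAGCGATCCTAGTGC   # 5'App (RNA-ligation) end first
rna_end: left
max_mismatches: 1
min_flank: 15
```

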