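# boilerplate

Lossy, coverage-domain compression of spliced RNA-seq alignments.

Instead of storing individual alignments, `boilerplate` groups a
coordinate-sorted SAM file into gene-scale **bundles** (reads starting within
50 bases of the running bundle end), cuts each bundle into **partitions** at
every observed splice site, and files each alignment into a **bucket** keyed by
the subset of partitions it spans, its `NH:i` multi-mapping count and its
`XS:A` strand tag. A bucket stores only a run-length-encoded coverage vector,
a tally of read lengths and (for paired data) a tally of genomic outer
distances (|TLEN|). Each bundle is DEFLATEd independently and indexed, so the
archive supports targeted queries without full decompression. Pairs that do
not fit a single bundle (intron-nested, cross-chromosome, distant, or
strand-discordant) are classified and either split, harmonized, or preserved
in a separately chunked and indexed *unbundled* section.

Decompression solves the **read recovery** problem per bucket with a greedy
left-to-right scan (exact when read lengths are uniform; heuristic with a
bounded lengthen/shorten repair otherwise — recovered coverage never exceeds
the stored vector) and then re-pairs recovered ends by walking inward from the
extremes, matching each read to the most distant partner whose outer distance
remains in the stored tally. Read names, sequences and qualities are discarded
by design; coverage is lossless, and aggregate length/distance distributions
are preserved while individual positions and pairings may be shuffled.

## CLI

```sh
# make a synthetic fixture (SAM + GTF + deterministic truth)
boilerplate synth --genes 20 --reads 5000 --paired --seed 1 \
    --out-sam reads.sam --out-gtf genes.gtf

# compress / decompress
boilerplate compress reads.sam reads.boil --seed 1
boilerplate decompress reads.boil restored.sam --seed 1

# queries (no full decompression)
boilerplate query reads.boil --mode bundles                 # BED
boilerplate query reads.boil --mode coverage --chrom chr1 --start 0 --end 5000   # bedGraph
boilerplate query reads.boil --mode alignments --chrom chr1 --start 0 --end 5000 # SAM

# fidelity metrics
boilerplate fidelity alignment-pr reads.sam restored.sam --mode ends
boilerplate fidelity alignment-pr reads.sam restored.sam --mode pairs
boilerplate fidelity transcript-pr ref.gtf assembled.gtf \
    --ref-coverage ref_cov.tsv --asm-coverage asm_cov.tsv -k 10
```

Compression options: `--preserve-nested` keeps intron-nested pairs paired,
`--split-discordant` splits strand-discordant pairs instead of harmonizing one
end's strand, and `--seed` drives every stochastic step (same input + same
seed ⇒ byte-identical archive). A `--config key=value` file can override
option defaults.

## Package layout

| module | role |
| --- | --- |
| `alignment_model` | normalized spliced-alignment records, CIGAR parsing, SAM I/O |
| `bundler` | bundle construction, unbundled-pair classification and policies |
| `compressor` | partitions, buckets, RLE, tallies, archive (de)serialization |
| `decompressor` | greedy read recovery and read pairing, bundle expansion |
| `query_engine` | bundle / coverage / alignment queries over the index |
| `fidelity` | alignment-level P/R, exon/transcript scores, TLEN ratios |
| `synthetic_data` | deterministic transcriptome + read simulator with truth side-data |
| `cli` | `boilerplate` command-line entry points |

## Caveats

- Not suitable for variant calling / allele-specific analyses: nucleotides,
  qualities and read names are discarded.
- Mixed read-length recovery is heuristic; with uniform-length input the
  alignment positions and shapes round-trip exactly.
- Pairings are restored to match the aggregate outer-distance distribution,
  not the original mate assignments.
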