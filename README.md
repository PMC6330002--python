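# qualcrunch

Reference-free **lossy compression of per-base quality values** in
coordinate-sorted SAM/BAM files.

Most base qualities in an aligned sequencing file are unnecessary for
downstream variant calling. `qualcrunch` runs a fast, deliberately
*pessimistic* diploid consensus caller over every pileup column (treating a
deletion as a fifth base type `*`) plus a set of unreliability heuristics,
and keeps qualities verbatim only where they may still matter:

* **kept verbatim** — inside retention-mask intervals (concordant soft
  clips, excessive depth, low mapping quality, >2 supported alleles,
  low-confidence consensus calls, short tandem repeats, each padded with
  context) and for whole reads that look misplaced;
* **flattened to one high constant** — bases agreeing with a confident
  consensus call;
* **constant-low / 8-bin quantized / kept** (configurable) — everything
  else (disagreeing bases, soft clips, insertions).

Kept stretches can optionally be smoothed with the greedy **P-block**
scheme (every output value within ±P of the original). A degenerate
full-retention mode is byte-lossless. All other record fields (sequence,
CIGAR, positions, flags, tags) pass through byte-identical; unmapped,
secondary, supplementary, duplicate and QC-fail records are never touched.

Processing is streamed window-by-window with overlap carry, so memory
stays bounded and a windowed run is byte-identical to a monolithic one.

## CLI

```sh
# compress (levels -1 conservative ... -9 aggressive; -9p8 adds P-block 8)
qualcrunch -9p8 in.bam out.bam
qualcrunch compress in.sam out.sam --level 9 --pblock 8 --drop-names
qualcrunch --tuned in.bam out.bam            # conf 60, mapq 30, depth 100
qualcrunch --lossless in.bam out.bam         # byte-identical qualities

# useful knobs
qualcrunch -9 --conf-threshold 60 --mapq-low 30 --depth-max 100 \
    --disagree-mode quantize --pad 10 --drop-aux OQ,BI in.bam out.bam

# synthetic data with a truth table
qualcrunch simulate sim.sam --ref-len 100000 --depth 30 --seed 1 \
    --truth truth.tsv

# quality-stream measurements (distinct symbols, order-0 entropy, gzip size)
qualcrunch stats in.sam out.sam
```

Per-window retention counts by reason go to stderr with `--verbose`; the
output header gains a `@PG` line recording the command.

## Package layout

| module | role |
| --- | --- |
| `qualcrunch.pileup` | read records, CIGAR expansion into pileup columns (`*` = deletion), soft-clip sites |
| `qualcrunch.consensus` | 15-genotype pessimistic diploid caller (vectorised + per-column APIs) |
| `qualcrunch.heuristics` | six retention detectors and the merged `RetentionMask` |
| `qualcrunch.rewrite` | quality rewriting, 8-bin quantizer, P-block smoothing |
| `qualcrunch.io_stream` | windowed streaming over SAM/BAM, writer with name/aux dropping |
| `qualcrunch.simulator` | truth-tracked read simulator (variants, STRs, clips, depth/MAPQ anomalies) |
| `qualcrunch.presets` | level 1–9 bundles, tuned and lossless profiles |
| `qualcrunch.cli` / `qualcrunch.stats` | command line and quality-stream metrics |
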