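# txseq

RNA-seq analysis toolkit for two-sample, no-replicate designs, built around
the stages of an embryo transcriptome study:

- **polyadenylation** — polyA-site calling from tail-bearing reads:
  terminal-run detection/trimming (≥6 A at 3' or ≥6 T at 5', trimmed length
  ≥25), unique remapping (≤1 mismatch) with a naive seed-and-extend aligner
  for toy genomes, internal-priming rejection (A≥6 run in the 10 bases
  downstream of the cleavage site), single-linkage clustering at ≤15 bp, and
  AAUAAA/AUUAAA signal annotation within 50 bp upstream.
- **expression** — constitutive-exon digital gene expression (base-level
  isoform intersection, whole-interval removal of cross-gene overlaps,
  entirely-contained fragment counting), exonic/intronic/intergenic
  accounting with the intronic-of-genic fraction, quantile normalization, a
  conditional negative-binomial exact test for two samples without
  replicates (mean–variance trend v = q + αq² fitted across features), and
  the closed-form pre-mRNA → intronic-read model
  f(p) = p(1−e)/(p+(1−p)e).
- **novel_tu** — coverage-island + junction-join assembly, the four-filter
  novel-TU definition (≥1000 bp from genes, ≥500 bp, ≥40 fragments/kb,
  <50% repeats), polyA/EST/conservation evidence annotation, and TU
  differential testing alongside genes.
- **splicing** — exon-skipping and alternative 5'/3' splice-site detection
  from junction counts (≥2 supporting fragments; 100% coverage between
  alternative sites), Fisher's exact test on inclusion/exclusion tables
  with BH FDR per event class.
- **enrichment** — hypergeometric GO over-representation with BH FDR over a
  flat gene→term map.
- **synthetic_data** — a seeded generator for toy genomes, annotations, and
  two-sample fragment/read sets: 3'-biased mature-transcript sampling,
  length-weighted pre-mRNA molecules (tunable per-sample fractions),
  polyA-tailed reads at true cleavage sites with planted signals and
  internal-priming artifacts, intergenic TUs with evidence flags and
  filter-failing decoys, planted differential expression and splicing
  events — all with complete truth tables.
- **io_formats / cli** — FASTA, GTF, SAM (text subset), BED6/BED12,
  bedGraph/wig, TSV readers/writers with one internal coordinate convention
  (0-based half-open), and a click CLI.

## CLI

```sh
# generate a synthetic two-sample dataset (with truth tables) and run
# every stage over it
txseq --seed 1 --outdir sim simulate
txseq --outdir results run --indir sim

# individual stages
txseq --outdir results polya --genome sim/genome.fa \
      --fastq sim/blastocysts.polya.fastq --fastq sim/degeneratives.polya.fastq
txseq --outdir results run --indir sim --only accounting
txseq --outdir results enrich --genes selected.txt \
      --annotations sim/go_annotations.tsv
```

All thresholds (tail run 6, trimmed length 25, cluster gap 15, signal
window 50, priming window 10, TU distance 1000 / length 500 / 40
fragments-per-kb / repeat 0.5, EST coverage 0.5, junction support 2, DE and
AS FDR 0.01, GO selection p 0.05, exon base fraction 1/20, insert size 122)
live in a flat key=value config file passed via `--config`; CLI flags
override it. `run` writes a `manifest.json`; reruns are byte-identical.

## Notes

- The protocol is unstranded: fragment strand is never inferred from
  alignment orientation; strand enters only via annotation, junction tables,
  or polyA-tail logic.
- The transcript assembler is intentionally simple (coverage islands joined
  by supported junctions); statistical path-significance assembly is an
  upstream concern, out of scope here.
- RPKM-style total-count normalization is deliberately absent; counts are
  quantile normalized.
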