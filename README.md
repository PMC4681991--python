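# rnfkit

Tools for benchmarking NGS read mappers with simulated reads whose **true
origin is encoded directly in the read name**.

Every read tuple (all reads from one DNA fragment) gets a *long read name*
(LRN) of four `__`-delimited parts — prefix, hexadecimal ID, a sorted block
of origin segments `(genome_id,chromosome_id,direction,left,right)`, and an
extension suffix — or, when the LRN would exceed 255 characters, a *short
read name* (`#` + hex ID) plus a row in an SRN–LRN correspondence TSV.
Coordinates are 1-based closed; `0` / direction `N` mean "unknown".

What's included:

- **`rnfkit.model`** — the name codec: encode/decode, validation, the
  LRN/SRN fallback policy and batch naming.
- **`rnfkit.dialects`** — converters from other simulators' naming
  conventions (wgsim-, dwgsim-, CuReSim-style name grammars; Art/Mason-style
  truth SAM files) into origin-named FASTQ. Grammars are configurable
  pattern files.
- **`rnfkit.simmix`** — a minimal built-in simulator (uniform substitution
  errors, single/paired) and a mixer that merges read sets with genome-ID
  re-assignment, for contamination / metagenome designs.
- **`rnfkit.liftover`** — transforms the coordinates inside read names with
  a UCSC chain file; ambiguous or gapped positions are zeroed, never
  approximated.
- **`rnfkit.evaluation`** — classifies each read's primary alignment
  against the truth in its name (correct / wrong position / mapped
  contaminant / unmapped…) and sweeps mapping-quality thresholds into
  sensitivity / precision / FDR curves.
- **`rnfkit.report`** — static HTML + SVG report; every plotted number is
  also in an adjacent TSV.
- **`rnfkit.fixtures`** — a deterministic toy world (two random genomes,
  read sets, scripted pseudo-mappers, chain files) used by the tests.

## CLI

```sh
rnfkit simulate ref.fa --n-reads 1000 --read-length 100 --seed 1 --out-dir sim/
rnfkit mix --sample sim/host.fq:1 --sample sim/cont.fq:2 --out-dir mixed/
rnfkit convert --dialect dwgsim -i reads.fq -o rnf.fq --genome-id 1
rnfkit convert --dialect sam -i truth.sam -o rnf.fq
rnfkit liftover --chain hg.chain -i rnf.fq -o lifted.fq --chrom-map map.tsv
rnfkit validate rnf.fq
rnfkit evaluate mapper1.sam mapper2.sam --genome-id 1 --tolerance 5 --out-dir eval/
rnfkit report eval/mapper1.curve.tsv --out-dir report/
rnfkit make-fixtures --seed 1 --out-dir fixtures/
```

`evaluate` writes one `<name>.curve.tsv` (per-threshold category counts,
sensitivity, precision, FDR) and one `<name>.reads.tsv` audit per input,
plus a combined HTML report with sensitivity-vs-FDR curves parametrized by
MAPQ. Chromosome name→ID maps are two-column TSVs; by default IDs follow
the 1-based order of appearance (FASTA records / `@SQ` headers).

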