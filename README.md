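# irrbs — RRBS end-repair artifact correction

Reduced Representation Bisulfite Sequencing (RRBS) enriches CpG-rich genomic
regions by MspI digestion (cut site `C^CGG`) followed by size selection and
bisulfite sequencing. Library preparation fills in the recessed 3′ fragment
ends across the 5′-CG overhang, adding an **unmethylated cytosine in CpG
context** plus a guanine. Adapter trimmers remove these bases when they can
see the adapter — but when a read's 3′ end coincides exactly with a genomic
MspI site (fragment length == read length), no adapter is present in the
read and the artificial cytosine survives into methylation calling. The
result: CpGs at fragment boundaries look hypomethylated, and comparisons
between libraries — especially libraries with *different read lengths* —
produce false differentially methylated sites (DMS) spaced almost exactly
one read length apart.

`irrbs` is a post-alignment, pre-methylation-calling correction for people
running RRBS pipelines (Trim Galore → bisulfite aligner → methylKit-style
analysis): it detects aligned reads whose biological 3′ end abuts a genomic
`CCGG` and blanks their three terminal methylation calls, so downstream
extractors never see the artifact. It also ships a directional RRBS
simulator with ground truth and diagnostics that make the artifact — and its
removal — measurable without any external data.

## The correction

Reads are represented with Bismark-style `XM` methylation-call strings
(`Z`/`z` = methylated/unmethylated CpG, `X`/`x` CHG, `H`/`h` CHH, `.` not a
cytosine). For each single-end or R1 candidate read (mapped, primary), take
its reference span `[s, e)` and strand, and test the 4-mer made of the last
three aligned bases plus one base further 3′:

- forward reads: genome window `[e−3, e+1)`
- reverse reads: genome window `[s−1, s+3)` (stored orientation is
  reference orientation, so the biological 3′ end is leftmost)

If the window equals `CCGG`, the read terminates in the end-repaired
`T·T·G` signature (the middle T being the converted fill-in cytosine) and
its three 3′-terminal `XM` characters are replaced by `.`. Nothing else —
sequence, coordinates, flags, qualities — changes. Unique mapping loci are
evaluated once ("MspI blocks") instead of per read; a property test certifies
that this optimization is exactly equivalent to per-read evaluation. R2 reads
need no action: their biased bases sit at their 5′ end and are already
trimmed upstream.

## Worked example

```python
from irrbs.methylation_summary import call_cpg_methylation
from irrbs.mspi_masker import mask_bam
from irrbs.rrbs_simulator import (SimConfig, bias_exposed_units,
                                  make_structured_genome, simulate_reads,
                                  spacing_for_filled)

genome = make_structured_genome([spacing_for_filled(50)] * 30, seed=11)
config = SimConfig(read_length=50, depth=50, seed=11, cpg_level=0.8)
simulate_reads(config, genome, "raw.bam")
mask_bam("raw.bam", genome, None, "masked.bam")
```

Running `python examples/02_methylation_bias.py` (the script behind the
snippet) prints:

```
simulated methylation level:              0.800
bias-exposed CpGs:                        31
mean beta at bias-exposed CpGs, raw:      0.404
mean beta at bias-exposed CpGs, masked:   0.807
mean beta at all other CpGs, raw:         0.804
```

Every CpG was simulated at 80% methylation, but the unmethylated fill-in
calls halve the apparent methylation of the 31 CpGs sitting on MspI
boundaries of full-length fragments; masking restores them to the simulated
level while all other CpGs are untouched. `examples/01_simulate_and_mask.py`
shows the read-level view (masked reads ≡ truth artifact reads, 3′-TTG
audit) and `examples/03_false_dms.py` the cohort-level view: comparing a
50 bp library against a 100 bp library of the *same* methylome yields DMS
exclusively at bias-exposed CpGs, paired ~48 and ~98 bp apart, and masking
eliminates every one of them.

## Command line

```bash
irrbs mask -i sorted.bam -c genome.chrom.sizes -g genome.fa -o masked.bam [--stats stats.json]
irrbs simulate --config sim.yaml --outdir out/ --seed 1
irrbs methylation -i masked.bam -o sample.cov [--no-destrand]
irrbs diagnose ttg|distances|dms ...
```

`mask` consumes a coordinate-sorted BAM plus the reference FASTA and
chrom.sizes table, and writes a BAM identical except for the masked `XM`
strings (a `ZM` tag marks corrected reads). `methylation` emits a
Bismark-coverage-style TSV; `diagnose dms` runs the simplified differential
test (pooled Fisher exact + Benjamini–Hochberg, coverage ≥ 10, q < 0.01 by
default).

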