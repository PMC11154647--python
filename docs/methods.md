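# Methods

## The artifact model

MspI cuts `C^CGG` on both strands, leaving 5′-CG overhangs. For a fragment
between two sites whose first-C coordinates are `a` and `b` (0-based), the
double-stranded molecule after digestion is:

- top strand: genomic positions `a+1 … b`
- bottom strand: genomic positions `a+3 … b+2`

End repair extends each recessed 3′ end across the opposite overhang: the
top strand gains a cytosine aligned to `b+1` and a guanine aligned to `b+2`;
the bottom strand gains a guanine at `a+1` and a cytosine at `a+2`. The
filled fragment therefore spans `[a+1, b+3)` on both strands, with filled
length `F = b − a + 2`. The fill-in cytosines are (essentially always)
unmethylated, yet each sits in a genuine genomic CpG context: the internal
CG of the downstream site (top-strand C at `b+1`) and of the upstream site
(bottom-strand C at `a+2`, which destranding folds onto `a+1`). Those two
CpG units per fragment are the *bias-exposed* units; they are `F − 2` apart,
which is why false DMS appear spaced just under the read length.

After bisulfite conversion the fill-in cytosine reads as T, so an untrimmed
artifact read ends, in sequencing orientation, with the trinucleotide
`T·T·G` and the terminal methylation calls `…x z .` — an unmethylated CHG
at the site's outer C, the biased unmethylated CpG, and the terminal G.

## The masking rule

The correction targets exactly the reads whose biological 3′-terminal base
aligns to the final fill base (`b+2` on top, `a+1` after mirroring on the
bottom strand). Those are the reads for which the 4-mer consisting of the
last three aligned reference positions plus one downstream base equals
`CCGG`:

- forward read with span `[s, e)`: window `[e−3, e+1)`
- reverse read: window `[s−1, s+3)`

Windows leaving the chromosome are non-matches. Candidates are mapped,
primary, non-supplementary single-end or R1 records; strand comes from flag
`0x10` (always present, unlike bisulfite bookkeeping tags). Matching reads
have their three 3′-terminal `XM` characters set to `.`, the symbol
downstream methylation extractors ignore. The mask deliberately covers three
positions: it also blanks a genuine CHG call at the site's outer C, which is
irrelevant to CpG analysis, and the terminal G, which carries no call.
Masking is idempotent and touches no other field.

Implementation: two streaming passes over a coordinate-sorted BAM. Pass one
collects unique `(chrom, span, strand)` loci of candidate reads and
evaluates each against the genome once (loci that match are "MspI blocks");
pass two rewrites every record, masking candidates whose locus is a block.
Keying loci by strand matters because the two strands of one span have
different 3′ windows. The unique-locus pass is purely an optimization; the
test suite proves it equivalent to brute-force per-read evaluation on random
genomes and reads. Reads whose strand-aware 3′-terminal CIGAR operation is
not an alignment match of length ≥ 3 (terminal soft clip, insertion or
deletion) are skipped and counted: the three-character mask would not map
cleanly onto reference positions, and skipping is the conservative choice.

A read whose last aligned base is the fill-in cytosine itself (fragment
filled length = read length + 1; the read ends `…TT` with no terminal G)
carries the bias but not the CCGG-terminus signature, and is deliberately
not masked: the signature rule cannot distinguish it from a genuine `…TT`
terminus. The simulator labels such reads `covers_fill` so their effect can
be measured; under realistic fragment-length spectra they are a small
minority of biased reads.

## The simulator

`rrbs_simulator` emulates a directional RRBS library with known truth:
in-silico MspI digestion (terminal fragments without two MspI ends are
discarded), size selection on the *filled* fragment length (the molecule
entering adapter ligation), per-molecule Bernoulli sampling of cytosine
states from a per-CpG methylome, fill-in cytosines sampled from their own
(default 0) methylation rate, per-strand bisulfite conversion, and read
construction in the three fragment-vs-read-length regimes:

- `F == read_length`: the read covers the whole filled fragment, fill bases
  included — trimming cannot detect the end repair (artifact);
- `F < read_length`: the adapter is sequenced, so emulated trimming removes
  it together with the two end-repair bases (read = genomic fragment only);
- `F > read_length`: the read is the 5′-most `read_length` bases and stops
  short of the fill-in (except the `F = read_length + 1` leak noted above).

Reads are emitted as already-aligned, coordinate-sorted BAM records with
`XM`/`XG`/`XR` tags computed from genomic context; alignment is bypassed on
purpose, so coordinates are exact truth and the masker is tested against a
standard BAM regardless of producer. In paired mode R2 covers the opposite
fragment end with its biased 5′ bases already removed, mirroring what an
`--rrbs`-style trimmer does, so correct behavior on R2 is "change nothing".
Only the directional protocol is modeled: R1 from the original top/bottom
strands, their complements appearing only as R2 templates.

Defaults describe a typical mammalian RRBS experiment and are the study
conditions throughout the tests: global CpG methylation 0.8, non-CpG
methylation 0, unmethylated fill-in, conversion rate 1.0, size selection
40–220 bp (a standard gel cut), read length 50. Structured genomes place
CCGG sites at chosen spacings (filled length = gap + 6) separated by
CCGG-free, CpG-bearing sequence — random CG-enriched by default, or a
deterministic `AACG` tiling when a test needs exact control of sequence
content (that tiling can never produce a post-conversion `TTG`
trinucleotide, keeping the TTG audit exact).

What the simulator does **not** model: sequencing errors and quality scores,
mapping ambiguity or soft clipping, adapter read-through, incomplete size
selection, PBAT/non-directional chemistry, SNPs, or copy-number variation.
Consequently the exact-recovery results (precision = recall = 1, zero
post-mask DMS) demonstrate the correctness of the algorithm's geometry, not
the false-positive rate on real data, where closely spaced MspI sites and
SNPs can cause a small amount of legitimate masking of genuine CpGs.

## Methylation calling and the differential test

`call_cpg_methylation` counts `Z`/`z` characters from the `XM` string — the
exact information downstream extractors consume, so masked positions vanish
by construction. The strand a call reports on comes from the `XG` tag
(`CT` top / `GA` bottom; flag fallback), and destranding (default on) folds
bottom-strand observations at `p` onto the top-strand C at `p−1`. Duplicates
are included: RRBS fragment ends are fixed by the digestion, so duplicate
flags cannot distinguish PCR copies from independent molecules. Output
round-trips through a Bismark-coverage-style TSV (1-based, methylation
percentage at ≥ 4 significant digits).

`simple_dms` is a deliberately minimal stand-in for logistic-regression DMS
callers: a CpG is testable when ≥ `min_samples` samples per group reach
coverage ≥ `min_cov` (default 10, mirroring common practice); counts are
pooled within group over the qualifying samples; a two-sided Fisher exact
test on the 2×2 methylated/unmethylated × group table gives p-values, and
Benjamini–Hochberg adjustment gives q-values gated at q < 0.01. A minimum
absolute methylation difference is exposed but defaults to 0 (effect-size
thresholds are conventionally applied to regions, not single sites).
Over-dispersion correction and region-level (tiling-window) analysis are out
of scope.

## Experiment geometries and problem sizes

Sizes were chosen by a-priori power calculation so that each property is
decided with large margins at modest cost; the full suite runs in well under
a minute.

- **Oracle equivalence**: 20 random genomes of 20–50 kb (30% G+C per base,
  giving hundreds of CCGG sites), 1000 reads each, one third anchored at
  site termini so true positives abound; masked-name sets must match the
  brute-force check exactly.
- **Bias removal / recovery**: 100 adjacent fragments of filled length 50,
  depth 100 per fragment end, `AACG` gaps. Interior bias-exposed units then
  receive 200 biased plus 200 genuine observations; pooled pre-mask
  methylation at those units is ~0.40 against a truth of 0.80 (one-sided
  binomial p ≪ 1e−6), and post-mask estimates must fall within 3 binomial
  standard errors of truth for ≥ 99% of CpGs.
- **False-DMS elimination**: groups of 3 samples at read lengths 50 vs 100,
  depth 25, one shared methylome (β = 0.8). The genome alternates biasable
  fragments (filled 50 or 100) with long spacer fragments (filled 304) whose
  CpGs sit in a central zone neither read length reaches, so every testable
  CpG is an MspI-boundary unit; this makes "all pre-mask DMS are
  bias-exposed" a sharp claim rather than a statistical one. Expected
  per-unit Fisher p-values are ~1e−7 against a Benjamini–Hochberg threshold
  three orders of magnitude larger. Post-mask the groups are exchangeable
  and the DMS count must be 0.
- **Null calibration**: identical configurations (read length 100, depth
  10, 3 samples per group) over 45 fragments with `AACG` gaps, ~1080
  testable CpGs; after masking, the fraction at q < 0.01 must not exceed
  0.01 (Benjamini–Hochberg controls the familywise error under the global
  null, and the Fisher test is conservative, so the observed fraction is
  essentially always 0).

`scripts/acceptance.py` re-runs these same geometries end-to-end, deriving
every random seed from its `--seed` argument, and reports the measured
quantities as JSON.

## Known limitations

- The masking rule requires the terminal G of the CCGG signature; the
  one-base-short leak case described above is detected (truth labels) but
  not corrected.
- Genuine methylation differences located exactly at bias-exposed CpGs are
  partially masked away along with the artifact — the cost of removing the
  fill-in observation is losing the true 3′-terminal observation of that
  unit on that fragment; coverage from neighboring fragments and the
  opposite strand usually remains.
- The FASTA loader keeps genomes in memory; for mammalian-scale references
  this costs a few GB. Lowercase (soft-masked) sequence is uppercased, and
  IUPAC ambiguity codes other than N are mapped to N with a warning.
- `simple_dms` pools counts within groups and therefore ignores
  between-sample over-dispersion; it is a demonstration statistic, not a
  replacement for a dispersion-aware caller.
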