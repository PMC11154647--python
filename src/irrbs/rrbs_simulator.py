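"""Directional RRBS library simulator with ground truth.

Emulates the wet-lab steps that create the end-repair artifact:

1. MspI digestion at CCGG (cut C^CGG on both strands, leaving 5'-CG
   overhangs). A fragment between adjacent sites with first-C coordinates
   ``a`` and ``b`` has top strand ``genome[a+1..b]``.
2. 3' fill-in across the overhangs: the top strand gains a cytosine at
   ``b+1`` and a guanine at ``b+2``; the bottom strand gains a guanine at
   ``a+1`` and a cytosine at ``a+2``. The fill-in cytosines are unmethylated
   (rate configurable), regardless of the true methylation of the CpG unit
   they sit in. Filled fragment length is ``b - a + 2``.
3. Size selection on the filled length.
4. Bisulfite conversion per strand: unmethylated C is read as T.
5. Sequencing at a fixed read length L in one of three regimes:

   * ``filled_len == L``: the read covers the whole filled fragment
     including both fill bases — trimming cannot detect the end repair
     (no adapter in the read) and the biased call survives (artifact).
   * ``filled_len < L``: the adapter is sequenced, so trimming removes it
     plus the two end-repair bases; the read is the genomic fragment only.
   * ``filled_len > L``: the read is the 5'-most L bases and normally never
     reaches the fill-in (when ``filled_len == L + 1`` the last read base is
     the fill-in cytosine itself; such a read carries the bias but lacks the
     terminal G signature, so it is recorded as ``covers_fill`` without the
     ``artifact`` flag).

Reads are emitted as already-aligned, coordinate-sorted BAM records with
Bismark-style XM/XG/XR tags computed from the genomic context (alignment is
bypassed: coordinates are truth). Directional protocol: R1 comes from the
original top (forward flag) and original bottom (reverse flag) strands; in
paired mode R2 covers the opposite fragment end with its biased 5' bases
already removed, so it needs — and receives — no correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .genome_model import MSPI_SITE, ReferenceGenome, find_mspi_sites

log = logging.getLogger(__name__)

_DEFAULT_QUAL = 40


@dataclass(frozen=True)
class Fragment:
    """An MspI-MspI fragment; ``a``/``b`` are first-C indices of the flanking
    CCGG sites, with no CCGG strictly between them."""

    chrom: str
    a: int
    b: int

    @property
    def top_start(self) -> int:
        return self.a + 1

    @property
    def top_end_genomic(self) -> int:  # inclusive
        return self.b

    @property
    def filled_len(self) -> int:
        return self.b - self.a + 2


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated library.

    Defaults describe a typical directional mammalian RRBS experiment:
    80% CpG methylation, no non-CpG methylation, unmethylated fill-in,
    complete bisulfite conversion, 40-220 bp size selection.
    """

    read_length: int = 50
    depth: int = 10  # molecules per fragment end (per strand)
    paired: bool = False
    cpg_level: float = 0.8
    per_cpg_levels: dict | None = None  # (chrom, top-C pos) -> level override
    non_cpg_level: float = 0.0
    fill_in_level: float = 0.0
    conversion_rate: float = 1.0
    size_min: int = 40
    size_max: int = 220
    seed: int = 0
    sample_name: str = "sample"

    def __post_init__(self) -> None:
        if self.read_length < 5:
            raise ValueError("read_length must be >= 5")
        if self.size_min > self.size_max:
            raise ValueError("size_min must be <= size_max")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        for name in ("cpg_level", "non_cpg_level", "fill_in_level", "conversion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated BAM."""

    reads: pd.DataFrame  # per emitted record
    cpgs: pd.DataFrame  # chrom, pos (top-C), level

    def write(self, reads_path: str | Path, cpgs_path: str | Path) -> None:
        self.reads.to_csv(reads_path, sep="\t", index=False)
        self.cpgs.to_csv(cpgs_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genome construction and digestion
# ---------------------------------------------------------------------------

#: CpG-bearing 4-mer used for deterministic gap content; CCGG-free in any
#: tiling and junction with CCGG blocks, and never yields a post-conversion
#: TTG trinucleotide.
STRUCTURED_GAP_PATTERN = "AACG"


def spacing_for_filled(filled_len: int) -> int:
    """Inter-site gap producing a given filled fragment length (= gap + 6)."""
    if filled_len < 7:
        raise ValueError("filled_len must be >= 7")
    return filled_len - 6


def _random_gap(length: int, rng: np.random.Generator, cpg_weight: float) -> str:
    # CG-enriched random sequence with CCGG occurrences scrubbed.
    p_cg = min(max(cpg_weight, 0.0), 0.45)
    p_other = (1.0 - 2 * p_cg) / 2
    bases = rng.choice(list("ACGT"), size=length, p=[p_other, p_cg, p_cg, p_other])
    seq = "".join(bases)
    while True:
        i = seq.find(MSPI_SITE)
        if i == -1:
            return seq
        seq = seq[:i] + "A" + seq[i + 1 :]


def _patterned_gap(length: int, pattern: str) -> str:
    reps = length // len(pattern) + 1
    return (pattern * reps)[:length]


def make_structured_genome(
    spacings: Sequence[int],
    seed: int = 0,
    chrom: str = "chrS",
    pad: int = 12,
    gap_pattern: str | None = None,
    cpg_weight: float = 0.2,
) -> ReferenceGenome:
    """Single-chromosome genome with CCGG sites separated by given gaps.

    A gap of ``g`` bases between two CCGG blocks yields a filled fragment
    length of ``g + 6``. Gaps are CCGG-free and CpG-containing: random
    CG-enriched sequence by default, or a deterministic tiling of
    ``gap_pattern``. Deterministic per seed.
    """
    if any(g < 1 for g in spacings):
        raise ValueError("all spacings must be >= 1")
    rng = np.random.default_rng(seed)

    def gap(n: int) -> str:
        if gap_pattern is not None:
            return _patterned_gap(n, gap_pattern)
        return _random_gap(n, rng, cpg_weight)

    parts = [gap(pad)]
    if spacings is not None:
        parts.append(MSPI_SITE)
        for g in spacings:
            parts.append(gap(g))
            parts.append(MSPI_SITE)
    parts.append(gap(pad))
    seq = "".join(parts)
    assert seq.count(MSPI_SITE) >= len(spacings)
    return ReferenceGenome({chrom: seq})


def digest(genome: ReferenceGenome) -> list[Fragment]:
    """In-silico MspI digestion: one fragment per adjacent site pair.

    Terminal sub-sequences before the first and after the last site are
    discarded (they have at most one MspI end and never carry the artifact).
    """
    fragments: list[Fragment] = []
    for chrom in genome.chromosomes():
        sites = [s.pos for s in find_mspi_sites(genome, chrom)]
        fragments.extend(
            Fragment(chrom, a, b) for a, b in zip(sites, sites[1:])
        )
    return fragments


def build_methylome(genome: ReferenceGenome, config: SimConfig) -> dict:
    """True methylation level for every CpG unit (keyed by top-C position)."""
    methylome: dict[tuple[str, int], float] = {}
    overrides = config.per_cpg_levels or {}
    for chrom in genome.chromosomes():
        seq = genome.sequences[chrom]
        i = seq.find("CG")
        while i != -1:
            methylome[(chrom, i)] = overrides.get((chrom, i), config.cpg_level)
            i = seq.find("CG", i + 1)
    return methylome


# ---------------------------------------------------------------------------
# molecule-level sampling
# ---------------------------------------------------------------------------


def _sample_molecule_calls(
    seq: str,
    frag: Fragment,
    strand: str,
    config: SimConfig,
    methylome: dict,
    rng: np.random.Generator,
) -> dict[int, tuple[str, str]]:
    """Sample methylation/conversion for every cytosine of one molecule.

    Returns reference position -> (stored base, XM character), both in
    reference orientation, over the filled span [a+1, b+3). Positions without
    a cytosine on this strand are absent (stored base = genome base, XM '.').
    """
    a, b = frag.a, frag.b
    n = len(seq)
    calls: dict[int, tuple[str, str]] = {}
    for p in range(a + 1, b + 3):
        if strand == "+":
            if seq[p] != "C":
                continue
            if p + 1 < n and seq[p + 1] == "G":
                ctx = "Z"
                level = (
                    config.fill_in_level
                    if p == b + 1
                    else methylome[(frag.chrom, p)]
                )
            elif p + 2 < n and seq[p + 2] == "G":
                ctx, level = "X", config.non_cpg_level
            else:
                ctx, level = "H", config.non_cpg_level
        else:
            if seq[p] != "G":
                continue
            if p >= 1 and seq[p - 1] == "C":
                ctx = "Z"
                level = (
                    config.fill_in_level
                    if p == a + 2
                    else methylome[(frag.chrom, p - 1)]
                )
            elif p >= 2 and seq[p - 2] == "C":
                ctx, level = "X", config.non_cpg_level
            else:
                ctx, level = "H", config.non_cpg_level
        methylated = rng.random() < level
        observed_c = methylated or rng.random() >= config.conversion_rate
        if strand == "+":
            base = "C" if observed_c else "T"
        else:  # bottom-strand C appears as G (retained) or A (converted)
            base = "G" if observed_c else "A"
        calls[p] = (base, ctx if observed_c else ctx.lower())
    return calls


def _render(
    seq: str, span: tuple[int, int], calls: dict[int, tuple[str, str]]
) -> tuple[str, str]:
    """Stored (reference-orientation) SEQ and XM over a span."""
    bases, xm = [], []
    for p in range(*span):
        if p in calls:
            b, c = calls[p]
        else:
            b, c = seq[p], "."
        bases.append(b)
        xm.append(c)
    return "".join(bases), "".join(xm)


def _r1_span(frag: Fragment, strand: str, L: int) -> tuple[tuple[int, int], str]:
    """R1 reference span and regime name for one fragment/strand."""
    a, b, F = frag.a, frag.b, frag.filled_len
    if F == L:
        regime = "full"
        span = (a + 1, b + 3)
    elif F < L:
        regime = "trimmed"
        span = (a + 1, b + 1) if strand == "+" else (a + 3, b + 3)
    else:
        regime = "truncated"
        span = (a + 1, a + 1 + L) if strand == "+" else (b + 3 - L, b + 3)
    return span, regime


def _r2_span(frag: Fragment, strand: str, L: int) -> tuple[int, int]:
    """R2 span: opposite fragment end, biased 5' bases already trimmed."""
    a, b = frag.a, frag.b
    if strand == "+":  # R2 reads back from the filled 3' end; fill trimmed
        return (max(a + 1, b + 1 - L), b + 1)
    return (a + 3, min(b + 3, a + 3 + L))


def _covers_fill(frag: Fragment, strand: str, span: tuple[int, int]) -> bool:
    fill = (frag.b + 1, frag.b + 2) if strand == "+" else (frag.a + 1, frag.a + 2)
    return any(span[0] <= p < span[1] for p in fill)


# ---------------------------------------------------------------------------
# read emission
# ---------------------------------------------------------------------------


def _bam_header(genome: ReferenceGenome) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": genome.lengths[c]} for c in genome.chromosomes()],
            "PG": [{"ID": "irrbs-sim", "PN": "irrbs", "CL": "irrbs simulate"}],
        }
    )


def _make_record(
    header: pysam.AlignmentHeader,
    qname: str,
    chrom: str,
    span: tuple[int, int],
    flag: int,
    seq: str,
    xm: str,
    xg: str,
    xr: str,
    mate_span: tuple[int, int] | None = None,
    tlen: int = 0,
) -> pysam.AlignedSegment:
    rec = pysam.AlignedSegment(header)
    rec.query_name = qname
    rec.flag = flag
    rec.reference_id = header.get_tid(chrom)
    rec.reference_start = span[0]
    rec.mapping_quality = _DEFAULT_QUAL
    rec.cigartuples = [(0, span[1] - span[0])]
    rec.query_sequence = seq
    rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    if mate_span is not None:
        rec.next_reference_id = rec.reference_id
        rec.next_reference_start = mate_span[0]
        rec.template_length = tlen
    else:
        rec.next_reference_id = -1
        rec.next_reference_start = -1
        rec.template_length = 0
    rec.set_tag("XM", xm, value_type="Z")
    rec.set_tag("XG", xg, value_type="Z")
    rec.set_tag("XR", xr, value_type="Z")
    return rec


def simulate_reads(
    config: SimConfig,
    genome: ReferenceGenome,
    out_bam: str | Path,
    methylome: dict | None = None,
    subseed: Sequence[int] | None = None,
) -> SimTruth:
    """Simulate one library into a coordinate-sorted BAM; return the truth.

    For each size-selected fragment and each original strand (top -> forward
    R1, bottom -> reverse R1), ``depth`` molecules are drawn. Identical
    config + seed gives byte-identical output. ``subseed`` extends the seed
    for multi-sample experiments.
    """
    if methylome is None:
        methylome = build_methylome(genome, config)
    rng = np.random.default_rng(
        config.seed if subseed is None else [config.seed, *subseed]
    )
    header = _bam_header(genome)
    L = config.read_length
    fragments = digest(genome)
    selected = [f for f in fragments if config.size_min <= f.filled_len <= config.size_max]
    if not selected:
        log.warning("no fragments survive size selection [%d, %d]",
                    config.size_min, config.size_max)

    records: list[tuple[int, int, int, pysam.AlignedSegment]] = []
    truth_rows: list[dict] = []
    order = 0

    def emit(rec: pysam.AlignedSegment, frag_id: int, strand: str, mate: int,
             regime: str, artifact: bool, covers: bool) -> None:
        nonlocal order
        records.append((rec.reference_id, rec.reference_start, order, rec))
        order += 1
        truth_rows.append(
            {
                "qname": rec.query_name,
                "mate": mate,
                "chrom": rec.reference_name,
                "start": rec.reference_start,
                "end": rec.reference_end,
                "fragment": frag_id,
                "strand": strand,
                "regime": regime,
                "artifact": artifact,
                "covers_fill": covers,
            }
        )

    for frag_id, frag in enumerate(selected):
        seq = genome.sequences[frag.chrom]
        for strand in "+-":
            span, regime = _r1_span(frag, strand, L)
            artifact = regime == "full"
            for m in range(config.depth):
                calls = _sample_molecule_calls(
                    seq, frag, strand, config, methylome, rng
                )
                qname = f"{config.sample_name}:f{frag_id}:{strand}:{m}"
                r1_seq, r1_xm = _render(seq, span, calls)
                xg = "CT" if strand == "+" else "GA"
                if config.paired:
                    mspan = _r2_span(frag, strand, L)
                    r1_flag = 99 if strand == "+" else 83
                    r2_flag = 147 if strand == "+" else 163
                    # leftmost segment gets the positive TLEN; R1 wins ties
                    extent = max(span[1], mspan[1]) - min(span[0], mspan[0])
                    t1 = extent if span[0] <= mspan[0] else -extent
                    rec1 = _make_record(
                        header, qname, frag.chrom, span, r1_flag,
                        r1_seq, r1_xm, xg, "CT", mate_span=mspan, tlen=t1,
                    )
                    r2_seq, r2_xm = _render(seq, mspan, calls)
                    rec2 = _make_record(
                        header, qname, frag.chrom, mspan, r2_flag,
                        r2_seq, r2_xm, xg, "GA", mate_span=span, tlen=-t1,
                    )
                    emit(rec1, frag_id, strand, 1, regime, artifact,
                         _covers_fill(frag, strand, span))
                    emit(rec2, frag_id, strand, 2, regime, False,
                         _covers_fill(frag, strand, mspan))
                else:
                    flag = 0 if strand == "+" else 16
                    rec1 = _make_record(
                        header, qname, frag.chrom, span, flag,
                        r1_seq, r1_xm, xg, "CT",
                    )
                    emit(rec1, frag_id, strand, 1, regime, artifact,
                         _covers_fill(frag, strand, span))

    records.sort(key=lambda t: (t[0], t[1], t[2]))
    with pysam.AlignmentFile(str(out_bam), "wb", header=header) as out:
        for *_, rec in records:
            out.write(rec)

    reads_df = pd.DataFrame(
        truth_rows,
        columns=["qname", "mate", "chrom", "start", "end", "fragment",
                 "strand", "regime", "artifact", "covers_fill"],
    )
    cpgs_df = pd.DataFrame(
        [{"chrom": c, "pos": p, "level": lv} for (c, p), lv in sorted(methylome.items())],
        columns=["chrom", "pos", "level"],
    )
    return SimTruth(reads=reads_df, cpgs=cpgs_df)


# ---------------------------------------------------------------------------
# two-group experiments
# ---------------------------------------------------------------------------


def bias_exposed_units(genome: ReferenceGenome, config: SimConfig) -> set[tuple[str, int]]:
    """CpG units (top-C coordinates) whose calls carry the end-repair bias.

    A fragment whose filled length equals the read length is sequenced
    end-to-end; its two fill-in cytosines report on the CpG units at ``b+1``
    (forward reads) and, after destranding, ``a+1`` (reverse reads). The two
    units of one fragment are ``filled_len - 2 = L - 2`` apart.
    """
    exposed: set[tuple[str, int]] = set()
    for frag in digest(genome):
        if not (config.size_min <= frag.filled_len <= config.size_max):
            continue
        if frag.filled_len == config.read_length:
            exposed.add((frag.chrom, frag.a + 1))
            exposed.add((frag.chrom, frag.b + 1))
    return exposed


@dataclass
class TwoGroupSim:
    bams_a: list[Path]
    bams_b: list[Path]
    truths_a: list[SimTruth] = field(repr=False, default_factory=list)
    truths_b: list[SimTruth] = field(repr=False, default_factory=list)
    bias_exposed_a: set = field(default_factory=set)
    bias_exposed_b: set = field(default_factory=set)
    methylome: dict = field(repr=False, default_factory=dict)


def _same_methylome_spec(a: SimConfig, b: SimConfig) -> bool:
    return (
        a.cpg_level == b.cpg_level
        and a.per_cpg_levels == b.per_cpg_levels
        and a.non_cpg_level == b.non_cpg_level
    )


def simulate_two_groups(
    config_a: SimConfig,
    config_b: SimConfig,
    n_per_group: int,
    genome: ReferenceGenome,
    outdir: str | Path,
) -> TwoGroupSim:
    """Simulate two sample groups sharing one genome and methylome.

    Typically the configs differ only in read length, reproducing the
    worst-case comparison where each group exposes a different set of CpG
    units to the end-repair bias.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if not _same_methylome_spec(config_a, config_b):
        raise ValueError("groups must share the methylome specification")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    methylome = build_methylome(genome, config_a)
    result = TwoGroupSim(
        bams_a=[],
        bams_b=[],
        bias_exposed_a=bias_exposed_units(genome, config_a),
        bias_exposed_b=bias_exposed_units(genome, config_b),
        methylome=methylome,
    )
    for gidx, (label, cfg, bams, truths) in enumerate(
        (("A", config_a, result.bams_a, result.truths_a),
         ("B", config_b, result.bams_b, result.truths_b))
    ):
        for i in range(n_per_group):
            cfg_i = replace(cfg, sample_name=f"{label}{i}")
            path = outdir / f"{label}{i}.bam"
            truth = simulate_reads(cfg_i, genome, path, methylome=methylome,
                                   subseed=(gidx, i))
            bams.append(path)
            truths.append(truth)
    return result
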