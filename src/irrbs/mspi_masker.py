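"""Mask end-repair-derived methylation calls at MspI-terminating read ends.

During RRBS library preparation the recessed 3' ends left by MspI digestion
are filled in with an (almost always unmethylated) cytosine plus a guanine.
When a read's 3' end coincides exactly with a genomic CCGG site, adapter
trimming cannot see the end-repair and the artificial cytosine survives into
methylation calling, depressing the apparent methylation of that CpG. This
module finds such reads and blanks their three terminal methylation calls so
downstream extractors ignore them; sequence, coordinates and every other
field are untouched.

Algorithm (two streaming passes over a coordinate-sorted BAM):

1. Collect the unique mapping loci (chrom, span, strand) of all candidate
   reads (single-end or R1, mapped, primary). Evaluate each locus once
   against the genome: it becomes an *MspI block* when the 4-mer made of its
   three 3'-terminal reference positions plus one downstream base is CCGG.
2. Rewrite every record; candidates whose locus is a block get their three
   3'-terminal XM characters (strand-aware) replaced by '.', the Bismark
   "not cytosine" symbol.

Unique-locus evaluation rather than per-read evaluation is a pure
optimization; the oracle-equivalence test certifies they agree.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable

import pysam

from . import __version__
from .alignment_model import (
    XM_TAG,
    is_candidate,
    reference_span,
    require_coordinate_sorted,
    terminal_three_aligned,
)
from .genome_model import (
    MSPI_SITE,
    ReferenceGenome,
    check_consistency,
    load_chrom_sizes,
    load_fasta,
)

log = logging.getLogger(__name__)

MASK_CHAR = "."
#: aux tag recording how many 3' calls were masked on a read
MASK_COUNT_TAG = "ZM"

Locus = tuple[str, int, int, str]  # chrom, start, end (half-open), strand


@dataclass
class MaskingStats:
    """Bookkeeping for one masking run."""

    reads_total: int = 0
    candidates: int = 0
    unique_loci: int = 0
    mspi_blocks: int = 0
    reads_masked: int = 0
    skipped_unmaskable: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def read_locus(read: pysam.AlignedSegment) -> Locus:
    start, end = reference_span(read)
    return (read.reference_name, start, end, "-" if read.is_reverse else "+")


def collect_unique_loci(reads: Iterable[pysam.AlignedSegment]) -> set[Locus]:
    """Distinct (chrom, span, strand) keys of candidate reads.

    Strand is part of the key because the 3' window of a locus differs
    between strands.
    """
    return {read_locus(r) for r in reads if is_candidate(r)}


def locus_window(locus: Locus) -> tuple[str, int, int]:
    chrom, start, end, strand = locus
    if strand == "-":
        return chrom, start - 1, start + 3
    return chrom, end - 3, end + 1


def locus_matches_mspi(locus: Locus, genome: ReferenceGenome) -> bool:
    """Whether the locus' stranded 3' terminus abuts a genomic CCGG.

    Out-of-bounds windows are simply not matches.
    """
    chrom, wstart, wend = locus_window(locus)
    if chrom not in genome.sequences:
        raise KeyError(f"chromosome {chrom!r} present in BAM but absent from genome")
    if wstart < 0 or wend > genome.lengths[chrom]:
        return False
    return genome.fetch(chrom, wstart, wend) == MSPI_SITE


def mask_read(read: pysam.AlignedSegment) -> pysam.AlignedSegment:
    """Blank the three biological-3'-terminal XM calls of ``read`` in place.

    Forward reads: last three stored characters; reverse reads: first three
    (SEQ/XM are stored in reference orientation). SEQ, POS, CIGAR, FLAG and
    QNAME are unchanged; a ZM aux tag records the mask width. Idempotent.
    Reads with XM shorter than 3 are left unmodified.
    """
    if not read.has_tag(XM_TAG):
        log.warning("read %s lacks an XM tag; not masked", read.query_name)
        return read
    xm = read.get_tag(XM_TAG)
    if len(xm) < 3:
        log.warning("read %s has XM shorter than 3; not masked", read.query_name)
        return read
    if read.is_reverse:
        xm = MASK_CHAR * 3 + xm[3:]
    else:
        xm = xm[:-3] + MASK_CHAR * 3
    read.set_tag(XM_TAG, xm, value_type="Z")
    read.set_tag(MASK_COUNT_TAG, 3, value_type="i")
    return read


def _maskable(read: pysam.AlignedSegment) -> bool:
    return (
        terminal_three_aligned(read)
        and read.has_tag(XM_TAG)
        and len(read.get_tag(XM_TAG)) >= 3
    )


def _resolve_genome(
    genome: str | Path | ReferenceGenome, chrom_sizes: str | Path | dict | None
) -> ReferenceGenome:
    if not isinstance(genome, ReferenceGenome):
        genome = load_fasta(genome)
    if chrom_sizes is not None:
        sizes = (
            chrom_sizes
            if isinstance(chrom_sizes, dict)
            else load_chrom_sizes(chrom_sizes)
        )
        check_consistency(genome, sizes)
    return genome


def _pg_header(header: pysam.AlignmentHeader) -> dict:
    hd = header.to_dict()
    hd.setdefault("PG", []).append(
        {"ID": "irrbs", "PN": "irrbs", "VN": __version__, "CL": "irrbs mask"}
    )
    return hd


def mask_bam(
    in_bam: str | Path,
    genome: str | Path | ReferenceGenome,
    chrom_sizes: str | Path | dict | None,
    out_bam: str | Path,
    stats_path: str | Path | None = None,
) -> MaskingStats:
    """Two-pass streaming correction of a coordinate-sorted BAM.

    Pass 1 collects unique candidate loci and marks those whose 3' window is
    CCGG as MspI blocks; pass 2 rewrites every record, masking exactly the
    candidates whose locus is a block. Record count and order are preserved;
    a PG line is appended to the header. Returns :class:`MaskingStats`.
    """
    ref = _resolve_genome(genome, chrom_sizes)
    stats = MaskingStats()

    with pysam.AlignmentFile(str(in_bam), check_sq=False) as bam:
        require_coordinate_sorted(bam)
        loci = collect_unique_loci(bam.fetch(until_eof=True))
    stats.unique_loci = len(loci)
    blocks = {loc for loc in loci if locus_matches_mspi(loc, ref)}
    stats.mspi_blocks = len(blocks)

    with pysam.AlignmentFile(str(in_bam), check_sq=False) as bam:
        header = _pg_header(bam.header)
        with pysam.AlignmentFile(str(out_bam), "wb", header=header) as out:
            for read in bam.fetch(until_eof=True):
                stats.reads_total += 1
                if is_candidate(read):
                    stats.candidates += 1
                    if read_locus(read) in blocks:
                        if _maskable(read):
                            mask_read(read)
                            stats.reads_masked += 1
                        else:
                            stats.skipped_unmaskable += 1
                out.write(read)

    if stats_path is not None:
        stats.to_json(stats_path)
    log.info(
        "masked %d/%d candidate reads (%d unique loci, %d MspI blocks, "
        "%d unmaskable skipped)",
        stats.reads_masked,
        stats.candidates,
        stats.unique_loci,
        stats.mspi_blocks,
        stats.skipped_unmaskable,
    )
    return stats
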