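"""Bisulfite alignment records and their interrogation.

Works directly on :class:`pysam.AlignedSegment`. Records are expected to
carry Bismark-style auxiliary tags: ``XM`` (per-base methylation-call string,
alphabet Z/z X/x H/h U/u '.'), and optionally ``XG``/``XR`` (bisulfite strand
bookkeeping, passed through untouched). For reverse-flag reads SEQ and XM are
stored in reference orientation, so the biological 3' end occupies the
leftmost stored positions.
"""

from __future__ import annotations

import pysam

XM_TAG = "XM"

#: CIGAR operations that consume reference bases: M, D, N, =, X
_REF_CONSUMING = frozenset((0, 2, 3, 7, 8))
#: CIGAR alignment-match operations: M, =, X
_ALIGN_MATCH = frozenset((0, 7, 8))


def reference_span(read: pysam.AlignedSegment) -> tuple[int, int]:
    """0-based half-open reference interval covered by the alignment.

    ``end - start`` equals the summed length of reference-consuming CIGAR
    operations; soft/hard clips and insertions contribute nothing.
    """
    if read.is_unmapped:
        raise ValueError(f"unmapped read has no reference span: {read.query_name}")
    return read.reference_start, read.reference_end


def is_candidate(read: pysam.AlignedSegment) -> bool:
    """Whether a record is eligible for MspI-terminus masking.

    Single-end reads and R1 of pairs qualify when mapped, primary and not
    supplementary. R2 never qualifies: its biased bases sit at its 5' end and
    are already trimmed upstream, while its 3' end copies the unbiased
    fragment 5' terminus. Duplicate-flagged reads remain candidates.
    """
    return (
        not read.is_unmapped
        and not read.is_secondary
        and not read.is_supplementary
        and (not read.is_paired or read.is_read1)
    )


def stranded_3prime_window(
    read: pysam.AlignedSegment, lengths: dict[str, int]
) -> tuple[str, int, int] | None:
    """The 4-base window whose CCGG match marks an end-repair terminus.

    The window consists of the read's last three aligned reference positions
    (strand-aware biological 3' end) plus one base further downstream:
    forward reads with span (s, e) -> [e-3, e+1); reverse reads -> [s-1, s+3).
    Returns None when the window would leave [0, chromosome length).
    """
    chrom = read.reference_name
    if chrom not in lengths:
        raise KeyError(f"chromosome {chrom!r} absent from lengths table")
    start, end = reference_span(read)
    if read.is_reverse:
        wstart, wend = start - 1, start + 3
    else:
        wstart, wend = end - 3, end + 1
    if wstart < 0 or wend > lengths[chrom]:
        return None
    return chrom, wstart, wend


def terminal_three_aligned(read: pysam.AlignedSegment) -> bool:
    """True when the biological 3'-terminal CIGAR op is an alignment match
    of length >= 3, i.e. the three terminal methylation calls map cleanly
    onto reference positions and may be masked."""
    cigar = read.cigartuples
    if not cigar:
        return False
    op, length = cigar[0] if read.is_reverse else cigar[-1]
    return op in _ALIGN_MATCH and length >= 3


def require_coordinate_sorted(bam: pysam.AlignmentFile) -> None:
    """Error unless the header declares coordinate sorting."""
    so = bam.header.to_dict().get("HD", {}).get("SO")
    if so != "coordinate":
        raise ValueError(
            f"input must be coordinate-sorted (header SO={so!r}); sort it first"
        )
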