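"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

from pathlib import Path

import pysam
import pytest

from irrbs.genome_model import ReferenceGenome

TOY_SEQ = "AACCGGTTTTCCGGAA"  # MspI sites at 2 and 10; one fragment (a=2, b=10)


@pytest.fixture
def toy_genome() -> ReferenceGenome:
    return ReferenceGenome({"chr1": TOY_SEQ})


def bam_header(lengths: dict[str, int], sort_order: str = "coordinate") -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": sort_order},
            "SQ": [{"SN": c, "LN": n} for c, n in lengths.items()],
        }
    )


def make_read(
    header: pysam.AlignmentHeader,
    qname: str = "r",
    flag: int = 0,
    chrom: str | None = "chr1",
    pos: int = 3,
    cigar: str = "10M",
    seq: str | None = None,
    xm: str | None = None,
    tags: dict | None = None,
    mapq: int = 40,
) -> pysam.AlignedSegment:
    rec = pysam.AlignedSegment(header)
    rec.query_name = qname
    rec.flag = flag
    if flag & 0x4 or chrom is None:
        rec.reference_id = -1
        rec.reference_start = -1
    else:
        rec.reference_id = header.get_tid(chrom)
        rec.reference_start = pos
        rec.mapping_quality = mapq
        rec.cigarstring = cigar
    if seq is None and not (flag & 0x4):
        seq = "A" * rec.infer_query_length()
    if seq is not None:
        rec.query_sequence = seq
        rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    if xm is not None:
        rec.set_tag("XM", xm, value_type="Z")
    for tag, value in (tags or {}).items():
        rec.set_tag(tag, value)
    return rec


def write_bam(path: str | Path, lengths: dict[str, int], reads, sort_order: str = "coordinate") -> Path:
    header = bam_header(lengths, sort_order)
    built = []
    for r in reads:
        built.append(make_read(header, **r) if isinstance(r, dict) else r)
    with pysam.AlignmentFile(str(path), "wb", header=header) as out:
        for rec in built:
            out.write(rec)
    return Path(path)


def read_bam(path: str | Path) -> list[pysam.AlignedSegment]:
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        return list(fh.fetch(until_eof=True))


_REF_CONSUMING = {0, 2, 3, 7, 8}  # M, D, N, =, X


def oracle_masked_names(bam_path: str | Path, sequences: dict[str, str]) -> set[str]:
    """Brute-force per-read CCGG-terminus check, independent of the package.

    Uses raw flag arithmetic, a direct CIGAR walk for the span, and a direct
    string comparison on the genome.
    """
    names: set[str] = set()
    with pysam.AlignmentFile(str(bam_path), check_sq=False) as fh:
        for r in fh.fetch(until_eof=True):
            f = r.flag
            if f & 0x4 or f & 0x100 or f & 0x800:
                continue
            if (f & 0x1) and not (f & 0x40):
                continue
            span = sum(n for op, n in (r.cigartuples or []) if op in _REF_CONSUMING)
            s = r.reference_start
            e = s + span
            seq = sequences[r.reference_name]
            if f & 0x10:
                ws, we = s - 1, s + 3
            else:
                ws, we = e - 3, e + 1
            if ws < 0 or we > len(seq):
                continue
            if seq[ws:we] == "CCGG":
                names.add(r.query_name)
    return names


def masked_names(bam_path: str | Path) -> set[str]:
    """Read names carrying the mask-count aux tag."""
    return {r.query_name for r in read_bam(bam_path) if r.has_tag("ZM")}
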