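"""Per-cytosine CpG methylation calling from XM-tagged BAMs.

Calls are taken from the XM string (what downstream extractors consume), not
by re-comparing SEQ to the genome, so masked ('.') positions contribute
nothing by construction. The strand a call reports on is taken from the
Bismark XG tag (CT = original top, GA = original bottom) with the reverse
flag as fallback; with destranding (default) bottom-strand observations at
position p are folded onto the top-strand C of their CpG unit at p-1.

Duplicates are included: RRBS fragment ends are fixed by the digestion, so
PCR-duplicate flags cannot distinguish duplicates from independent molecules.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import pysam

from .alignment_model import XM_TAG

log = logging.getLogger(__name__)

COVERAGE_COLUMNS = ["chrom", "pos", "strand", "count_meth", "count_unmeth", "beta"]


def call_cpg_methylation(bam: str | Path, destrand: bool = True) -> pd.DataFrame:
    """Count Z/z observations per CpG from an aligned, XM-tagged BAM.

    Secondary, supplementary and unmapped records are skipped; records
    lacking XM are skipped with a warning count. Returns a coordinate-sorted
    DataFrame with columns chrom, pos (0-based top-strand C when destranded),
    strand, count_meth, count_unmeth, beta.
    """
    counts: dict[tuple[str, int, str], list[int]] = {}
    missing_xm = 0
    with pysam.AlignmentFile(str(bam), check_sq=False) as fh:
        for read in fh.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if not read.has_tag(XM_TAG):
                missing_xm += 1
                continue
            xm = read.get_tag(XM_TAG)
            bottom = (
                read.get_tag("XG") == "GA"
                if read.has_tag("XG")
                else read.is_reverse
            )
            chrom = read.reference_name
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                call = xm[qpos]
                if call not in "Zz":
                    continue
                if bottom and destrand:
                    key = (chrom, rpos - 1, "+")
                else:
                    key = (chrom, rpos, "-" if bottom else "+")
                entry = counts.setdefault(key, [0, 0])
                entry[0 if call == "Z" else 1] += 1
    if missing_xm:
        log.warning("%d records lacked an XM tag and were skipped", missing_xm)
    rows = [
        {"chrom": c, "pos": p, "strand": s, "count_meth": m, "count_unmeth": u}
        for (c, p, s), (m, u) in sorted(counts.items())
    ]
    df = pd.DataFrame(rows, columns=COVERAGE_COLUMNS[:-1])
    if len(df):
        df["beta"] = df.count_meth / (df.count_meth + df.count_unmeth)
    else:
        df["beta"] = pd.Series(dtype=float)
    return df


def write_coverage(records: pd.DataFrame, path: str | Path) -> None:
    """Write a Bismark-coverage-style TSV.

    Columns: chrom, start (1-based), end (1-based, == start), methylation
    percentage (>= 4 significant digits), count_meth, count_unmeth.
    """
    with open(path, "w") as fh:
        for row in records.itertuples(index=False):
            total = row.count_meth + row.count_unmeth
            pct = 100.0 * row.count_meth / total if total else 0.0
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t{row.pos + 1}\t{pct:.6g}\t"
                f"{row.count_meth}\t{row.count_unmeth}\n"
            )


def read_coverage(path: str | Path) -> pd.DataFrame:
    """Read a Bismark-coverage TSV back into the internal representation
    (0-based positions, counts, beta recomputed from counts)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "pct", "count_meth", "count_unmeth"],
        dtype={"chrom": str},
    )
    out = pd.DataFrame(
        {
            "chrom": df.chrom,
            "pos": df.start - 1,
            "strand": "+",
            "count_meth": df.count_meth,
            "count_unmeth": df.count_unmeth,
        }
    )
    total = out.count_meth + out.count_unmeth
    out["beta"] = out.count_meth / total.where(total > 0)
    return out
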