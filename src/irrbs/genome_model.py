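"""Reference genome handling.

Loads FASTA references and UCSC ``chrom.sizes`` tables, normalizes sequences
to the {A,C,G,T,N} alphabet, and locates MspI recognition sites (``CCGG``).
All coordinates in this package are 0-based, half-open; conversion to the
1-based SAM / Bismark-coverage conventions happens only at I/O boundaries.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

from Bio import SeqIO

log = logging.getLogger(__name__)

MSPI_SITE = "CCGG"
VALID_BASES = frozenset("ACGTN")
#: IUPAC ambiguity codes other than N; mapped to N on load with a warning.
IUPAC_AMBIGUOUS = frozenset("RYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an {A,C,G,T,N} string."""
    return seq.translate(_COMPLEMENT)[::-1]


class MspISite(NamedTuple):
    """One CCGG occurrence; ``pos`` is the 0-based index of its first C."""

    chrom: str
    pos: int


@dataclass
class ReferenceGenome:
    """Uppercased reference sequences keyed by chromosome name."""

    sequences: dict[str, str]
    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.lengths:
            self.lengths = {c: len(s) for c, s in self.sequences.items()}

    def chromosomes(self) -> list[str]:
        return list(self.sequences)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence slice [start, end); raises on unknown chromosome."""
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome: {chrom!r}")
        return self.sequences[chrom][start:end]


def _normalize(seq: str, name: str) -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if not bad:
        return seq
    ambiguous = bad & IUPAC_AMBIGUOUS
    if bad - ambiguous:
        raise ValueError(
            f"non-nucleotide characters {sorted(bad - ambiguous)} in record {name!r}"
        )
    log.warning(
        "record %s: IUPAC ambiguity codes %s mapped to N", name, sorted(ambiguous)
    )
    return seq.translate(str.maketrans({c: "N" for c in ambiguous}))


def load_fasta(path: str | Path) -> ReferenceGenome:
    """Load a (possibly gzipped) multi-record FASTA into memory.

    Sequences are uppercased; IUPAC ambiguity codes other than N are mapped
    to N with a logged warning; duplicate record names are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    opener = gzip.open if path.suffix == ".gz" else open
    sequences: dict[str, str] = {}
    with opener(path, "rt") as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in sequences:
                raise ValueError(f"duplicate FASTA record name: {record.id!r}")
            sequences[record.id] = _normalize(str(record.seq), record.id)
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return ReferenceGenome(sequences)


def write_fasta(genome: ReferenceGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Parse a two-column ``chrom.sizes`` table (name, integer length)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            name = fields[0].strip()
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer length {fields[1].strip()!r}"
                ) from exc
            if name in sizes:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            sizes[name] = length
    if not sizes:
        raise ValueError(f"empty chrom.sizes file: {path}")
    return sizes


def write_chrom_sizes(genome: ReferenceGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def check_consistency(genome: ReferenceGenome, sizes: dict[str, int]) -> None:
    """Hard error when FASTA and chrom.sizes disagree (wrong genome build)."""
    if set(genome.lengths) != set(sizes):
        only_fa = sorted(set(genome.lengths) - set(sizes))
        only_cs = sorted(set(sizes) - set(genome.lengths))
        raise ValueError(
            "FASTA and chrom.sizes name different chromosomes "
            f"(FASTA only: {only_fa}, chrom.sizes only: {only_cs})"
        )
    for chrom, length in sizes.items():
        if genome.lengths[chrom] != length:
            raise ValueError(
                f"length mismatch for {chrom}: FASTA {genome.lengths[chrom]}, "
                f"chrom.sizes {length}"
            )


def find_mspi_sites(genome: ReferenceGenome, chrom: str) -> list[MspISite]:
    """All CCGG occurrences on ``chrom``, ascending, overlaps included.

    N never matches (no ambiguity expansion). CCGG is palindromic, so the
    same list serves both strands.
    """
    if chrom not in genome.sequences:
        raise KeyError(f"unknown chromosome: {chrom!r}")
    seq = genome.sequences[chrom]
    sites: list[MspISite] = []
    i = seq.find(MSPI_SITE)
    while i != -1:
        sites.append(MspISite(chrom, i))
        i = seq.find(MSPI_SITE, i + 1)
    return sites


def iter_all_mspi_sites(genome: ReferenceGenome) -> Iterable[MspISite]:
    for chrom in genome.chromosomes():
        yield from find_mspi_sites(genome, chrom)
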