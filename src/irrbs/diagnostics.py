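"""Artifact diagnostics: 3'-TTG audit, DMS distance spectra, simplified
differential methylation testing.

The end-repair artifact leaves two fingerprints. At the read level, biased
reads end (in sequencing orientation) with the trinucleotide TTG: the two
genomic Ts (or converted Cs) of the fragment terminus, the converted fill-in
cytosine, and the terminal fill-in guanine. At the cohort level, false
differentially methylated sites (DMS) appear in pairs spaced close to the
read length, visible as a spike in the distance distribution of neighboring
DMS.

The differential test is a deliberately simple stand-in for the logistic
regression used by full methylation pipelines: per CpG, counts are pooled
within group over samples meeting the coverage threshold, a two-sided Fisher
exact test is applied to the 2x2 (methylated/unmethylated x group) table,
and Benjamini-Hochberg adjustment gives q-values. It suffices to demonstrate
the appearance and removal of the artifactual DMS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_model import revcomp

log = logging.getLogger(__name__)

TTG = "TTG"


def ttg_fraction(bam: str | Path, read_length: int) -> float:
    """Fraction of full-length reads whose 3' trinucleotide is TTG.

    Only reads whose stored length equals ``read_length`` enter the
    denominator (shorter reads were trimmed and cannot carry the untrimmed
    artifact). The 3' trinucleotide is taken in sequencing orientation:
    last three stored bases for forward reads, reverse complement of the
    first three for reverse reads.
    """
    total = 0
    hits = 0
    with pysam.AlignmentFile(str(bam), check_sq=False) as fh:
        for read in fh.fetch(until_eof=True):
            seq = read.query_sequence
            if seq is None or len(seq) != read_length:
                continue
            total += 1
            tri = revcomp(seq[:3]) if read.is_reverse else seq[-3:]
            if tri == TTG:
                hits += 1
    return hits / total if total else 0.0


@dataclass
class DistanceSpectrum:
    """Distances between consecutive DMS positions within chromosomes."""

    distances: np.ndarray

    @property
    def histogram(self) -> pd.Series:
        if len(self.distances) == 0:
            return pd.Series(dtype=int, name="count")
        return (
            pd.Series(self.distances)
            .value_counts()
            .sort_index()
            .rename("count")
            .rename_axis("distance")
        )

    def fraction_at(self, distance: int) -> float:
        """Fraction of neighbor gaps equal to ``distance`` exactly."""
        if len(self.distances) == 0:
            return 0.0
        return float(np.mean(self.distances == distance))

    def fraction_in(self, lo: int, hi: int) -> float:
        """Fraction of neighbor gaps within [lo, hi] inclusive."""
        if len(self.distances) == 0:
            return 0.0
        return float(np.mean((self.distances >= lo) & (self.distances <= hi)))

    def write(self, path: str | Path) -> None:
        self.histogram.to_csv(path, sep="\t")


def neighbor_distance_spectrum(
    positions: Mapping[str, Sequence[int]] | pd.DataFrame,
) -> DistanceSpectrum:
    """Distances between consecutive positions within each chromosome.

    Accepts a DataFrame with chrom/pos columns or a mapping chrom -> sorted
    positions; unsorted input is an error. Distances never cross
    chromosomes.
    """
    if isinstance(positions, pd.DataFrame):
        groups = {
            chrom: sub["pos"].to_numpy()
            for chrom, sub in positions.groupby("chrom", sort=True)
        }
    else:
        groups = {c: np.asarray(p) for c, p in positions.items()}
    dists: list[np.ndarray] = []
    for chrom, pos in groups.items():
        pos = np.asarray(pos)
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"positions for {chrom} are not sorted ascending")
        if len(pos) > 1:
            dists.append(np.diff(pos))
    all_d = np.concatenate(dists) if dists else np.array([], dtype=int)
    return DistanceSpectrum(distances=all_d)


def _pool_group(
    tables: Sequence[pd.DataFrame], min_cov: int
) -> pd.DataFrame:
    """Pool counts per CpG over samples with coverage >= min_cov."""
    frames = []
    for i, t in enumerate(tables):
        t = t[["chrom", "pos", "count_meth", "count_unmeth"]].copy()
        cov = t.count_meth + t.count_unmeth
        t = t[cov >= min_cov]
        frames.append(t)
    merged = pd.concat(frames, ignore_index=True)
    pooled = (
        merged.groupby(["chrom", "pos"], sort=True)
        .agg(
            count_meth=("count_meth", "sum"),
            count_unmeth=("count_unmeth", "sum"),
            n_samples=("count_meth", "size"),
        )
        .reset_index()
    )
    return pooled


def simple_dms(
    group_a: Sequence[pd.DataFrame],
    group_b: Sequence[pd.DataFrame],
    min_cov: int = 10,
    min_samples: int = 1,
    q_thresh: float = 0.01,
    min_diff: float = 0.0,
) -> pd.DataFrame:
    """Per-CpG differential methylation between two sample groups.

    A CpG is testable when at least ``min_samples`` samples per group have
    coverage >= ``min_cov``; counts are pooled within group over the
    qualifying samples. Returns every testable CpG with beta_a, beta_b,
    diff = beta_a - beta_b, Fisher exact p, BH q, and a boolean ``dms``
    column (q < q_thresh and |diff| >= min_diff), sorted by coordinate.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must contain at least one sample")
    if min_samples > min(len(group_a), len(group_b)):
        raise ValueError("min_samples exceeds the size of a group")
    pa = _pool_group(group_a, min_cov)
    pb = _pool_group(group_b, min_cov)
    merged = pa.merge(pb, on=["chrom", "pos"], suffixes=("_a", "_b"))
    merged = merged[
        (merged.n_samples_a >= min_samples) & (merged.n_samples_b >= min_samples)
    ].reset_index(drop=True)
    if merged.empty:
        return pd.DataFrame(
            columns=["chrom", "pos", "beta_a", "beta_b", "diff", "p", "q", "dms"]
        )
    merged["beta_a"] = merged.count_meth_a / (merged.count_meth_a + merged.count_unmeth_a)
    merged["beta_b"] = merged.count_meth_b / (merged.count_meth_b + merged.count_unmeth_b)
    merged["diff"] = merged.beta_a - merged.beta_b
    pvals = np.empty(len(merged))
    for i, row in enumerate(merged.itertuples(index=False)):
        table = [
            [row.count_meth_a, row.count_unmeth_a],
            [row.count_meth_b, row.count_unmeth_b],
        ]
        pvals[i] = stats.fisher_exact(table, alternative="two-sided")[1]
    merged["p"] = pvals
    merged["q"] = multipletests(pvals, method="fdr_bh")[1]
    merged["dms"] = (merged.q < q_thresh) & (merged["diff"].abs() >= min_diff)
    out = merged[
        ["chrom", "pos", "beta_a", "beta_b", "diff", "p", "q", "dms"]
    ].sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return out


def write_dms(dms: pd.DataFrame, path: str | Path) -> None:
    """BED-like TSV of DMS records: chrom, start, end, diff, p, q."""
    flagged = dms[dms.dms] if "dms" in dms else dms
    with open(path, "w") as fh:
        for row in flagged.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t"
                f"{row.diff:.6g}\t{row.p:.6g}\t{row.q:.6g}\n"
            )


def plot_distance_spectrum(
    spectrum: DistanceSpectrum, path: str | Path, highlight: int | None = None
) -> None:
    """Histogram of neighbor distances; optional vertical marker at the
    read length where the artifact peak is expected."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    hist = spectrum.histogram
    if len(hist):
        ax.bar(hist.index, hist.values, width=1.0, color="steelblue")
    if highlight is not None:
        ax.axvline(highlight, color="firebrick", linestyle="--",
                   label=f"d = {highlight}")
        ax.legend()
    ax.set_xlabel("distance to next DMS (bp)")
    ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
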