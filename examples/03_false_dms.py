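"""False differentially methylated sites between libraries of different
read lengths, and their elimination.

Two groups share one methylome but are sequenced at 50 bp and 100 bp. Each
read length exposes a different set of MspI-boundary CpGs to the end-repair
bias, so a naive comparison calls those CpGs differentially methylated —
in pairs spaced (read length - 2) apart, the cohort-level fingerprint of the
artifact. After masking, the comparison is clean.
"""

import tempfile
from pathlib import Path

from irrbs.diagnostics import neighbor_distance_spectrum, simple_dms
from irrbs.methylation_summary import call_cpg_methylation
from irrbs.mspi_masker import mask_bam
from irrbs.rrbs_simulator import (
    SimConfig,
    make_structured_genome,
    simulate_two_groups,
    spacing_for_filled,
)

workdir = Path(tempfile.mkdtemp(prefix="irrbs_example_"))

# filled lengths 50 and 100 are biasable in one group each; 250 in neither
genome = make_structured_genome(
    [spacing_for_filled(f) for f in (50, 250, 100, 250)] * 6, seed=19,
    cpg_weight=0.08,
)
common = dict(depth=25, cpg_level=0.8, size_min=40, size_max=300)
cfg_a = SimConfig(read_length=50, seed=100, **common)
cfg_b = SimConfig(read_length=100, seed=200, **common)
sim = simulate_two_groups(cfg_a, cfg_b, 3, genome, workdir)


def coverage_tables(paths, mask_with=None):
    tables = []
    for p in paths:
        if mask_with is not None:
            dst = p.with_suffix(".masked.bam")
            mask_bam(p, mask_with, None, dst)
            p = dst
        tables.append(call_cpg_methylation(p))
    return tables


def dms_positions(a, b):
    res = simple_dms(a, b, min_cov=10, min_samples=3, q_thresh=0.01)
    return res[res.dms]


pre = dms_positions(coverage_tables(sim.bams_a), coverage_tables(sim.bams_b))
post = dms_positions(
    coverage_tables(sim.bams_a, mask_with=genome),
    coverage_tables(sim.bams_b, mask_with=genome),
)

exposed = sim.bias_exposed_a | sim.bias_exposed_b
on_bias = sum((c, p) in exposed for c, p in zip(pre.chrom, pre.pos))
spec = neighbor_distance_spectrum(pre[["chrom", "pos"]])

print(f"DMS before masking:                 {len(pre)}")
print(f"  located at bias-exposed CpGs:     {on_bias}")
print(f"  neighbor gaps at 48-50 bp:        {spec.fraction_in(48, 50):.2f}")
print(f"  neighbor gaps at 98-100 bp:       {spec.fraction_in(98, 100):.2f}")
print(f"DMS after masking:                  {len(post)}")
print()
print("Every pre-mask DMS sits on a CpG the simulator labeled bias-exposed,")
print("and consecutive DMS cluster at distances just under each group's")
print("read length. Masking removes them all; no true signal exists here,")
print("so zero post-mask DMS is the correct answer.")
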