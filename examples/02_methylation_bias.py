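"""Show the methylation bias at MspI-site CpGs and its removal.

Every CpG is simulated at 80% methylation. The fill-in cytosine added by end
repair is unmethylated, so before correction the CpGs adjacent to fragment
boundaries ("bias-exposed" units) appear roughly half as methylated as they
are. After masking, their estimates return to the simulated level.
"""

import tempfile
from pathlib import Path

from irrbs.methylation_summary import call_cpg_methylation
from irrbs.mspi_masker import mask_bam
from irrbs.rrbs_simulator import (
    SimConfig,
    bias_exposed_units,
    make_structured_genome,
    simulate_reads,
    spacing_for_filled,
)

workdir = Path(tempfile.mkdtemp(prefix="irrbs_example_"))

genome = make_structured_genome([spacing_for_filled(50)] * 30, seed=11)
config = SimConfig(read_length=50, depth=50, seed=11, cpg_level=0.8)

raw = workdir / "raw.bam"
simulate_reads(config, genome, raw)
masked = workdir / "masked.bam"
mask_bam(raw, genome, None, masked)

exposed = bias_exposed_units(genome, config)
pre = call_cpg_methylation(raw)
post = call_cpg_methylation(masked)


def mean_beta(df, units, invert=False):
    member = [((c, p) in units) != invert for c, p in zip(df.chrom, df.pos)]
    return df[member].beta.mean()


print(f"simulated methylation level:              0.800")
print(f"bias-exposed CpGs:                        {len(exposed)}")
print(f"mean beta at bias-exposed CpGs, raw:      {mean_beta(pre, exposed):.3f}")
print(f"mean beta at bias-exposed CpGs, masked:   {mean_beta(post, exposed):.3f}")
print(f"mean beta at all other CpGs, raw:         {mean_beta(pre, exposed, invert=True):.3f}")
print()
print("The unmethylated fill-in calls drag the raw estimate at fragment-")
print("boundary CpGs far below truth; masking the three 3'-terminal calls")
print("restores it while leaving every other CpG untouched.")
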