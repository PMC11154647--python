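import hashlib

import numpy as np
import pysam
import pytest

from irrbs.genome_model import MSPI_SITE, ReferenceGenome, revcomp
from irrbs.rrbs_simulator import (
    STRUCTURED_GAP_PATTERN,
    SimConfig,
    bias_exposed_units,
    build_methylome,
    digest,
    make_structured_genome,
    simulate_reads,
    simulate_two_groups,
    spacing_for_filled,
)

from conftest import TOY_SEQ, read_bam


def toy_config(**kw):
    base = dict(read_length=10, depth=1, cpg_level=0.0,
                per_cpg_levels={("chr1", 3): 1.0},
                size_min=5, size_max=50, seed=1)
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture
def toy_genome():
    return ReferenceGenome({"chr1": TOY_SEQ})


class TestStructuredGenome:
    def test_spacings_control_filled_lengths(self):
        spacings = [spacing_for_filled(50)] * 10
        g = make_structured_genome(spacings, seed=3)
        frags = digest(g)
        assert len(frags) == 10
        assert all(f.filled_len == 50 for f in frags)

    def test_empty_spacings_digest_to_nothing(self):
        g = make_structured_genome([], seed=0)
        assert digest(g) == []

    def test_deterministic_per_seed(self):
        a = make_structured_genome([20, 30], seed=5)
        b = make_structured_genome([20, 30], seed=5)
        c = make_structured_genome([20, 30], seed=6)
        assert a.sequences == b.sequences
        assert a.sequences != c.sequences

    def test_gaps_are_ccgg_free_and_cpg_bearing(self):
        g = make_structured_genome([50, 80, 120], seed=9)
        seq = g.sequences["chrS"]
        frags = digest(g)
        assert len(frags) == 3
        for f in frags:
            interior = seq[f.a + 4 : f.b]
            assert MSPI_SITE not in interior
            assert "CG" in interior

    def test_pattern_gaps(self):
        g = make_structured_genome([44], seed=0, gap_pattern=STRUCTURED_GAP_PATTERN)
        seq = g.sequences["chrS"]
        assert seq.count(MSPI_SITE) == 2

    def test_invalid_spacing(self):
        with pytest.raises(ValueError):
            make_structured_genome([0])


class TestDigest:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AACCGGTTTTCCGGAA", [(2, 10, 10)]),
            ("AACCGGTT", []),  # single site
            ("CCGGCCGG", [(0, 4, 6)]),  # adjacent sites
            ("CCGGTTCCGGTTTTCCGG", [(0, 6, 8), (6, 14, 10)]),
        ],
    )
    def test_fragments(self, seq, expected):
        frags = digest(ReferenceGenome({"c": seq}))
        assert [(f.a, f.b, f.filled_len) for f in frags] == expected

    def test_site_invariant(self):
        g = make_structured_genome([30, 60], seed=2)
        seq = g.sequences["chrS"]
        for f in digest(g):
            assert seq[f.a : f.a + 4] == MSPI_SITE
            assert seq[f.b : f.b + 4] == MSPI_SITE


class TestWorkedExample:
    """Fragment (a=2, b=10) of AACCGGTTTTCCGGAA, CpG at 3 methylated,
    everything else unmethylated, complete conversion."""

    def test_full_length_reads(self, tmp_path, toy_genome):
        bam = tmp_path / "s.bam"
        truth = simulate_reads(toy_config(), toy_genome, bam)
        fwd, rev = read_bam(bam)
        assert (fwd.reference_start, fwd.reference_end) == (3, 13)
        assert fwd.query_sequence == "CGGTTTTTTG"
        assert fwd.get_tag("XM") == "Z......xz."
        assert not fwd.is_reverse
        assert rev.is_reverse
        assert (rev.reference_start, rev.reference_end) == (3, 13)
        assert rev.query_sequence.startswith("CAA")
        assert rev.get_tag("XM").startswith(".zx")
        assert truth.reads.artifact.all()

    def test_trimmed_regime_removes_fill_bases(self, tmp_path, toy_genome):
        bam = tmp_path / "s.bam"
        truth = simulate_reads(toy_config(read_length=12), toy_genome, bam)
        fwd, rev = read_bam(bam)
        assert (fwd.reference_start, fwd.reference_end) == (3, 11)
        assert (rev.reference_start, rev.reference_end) == (5, 13)
        assert not truth.reads.artifact.any()
        assert not truth.reads.covers_fill.any()
        assert (truth.reads.regime == "trimmed").all()

    def test_truncated_regime(self, tmp_path, toy_genome):
        bam = tmp_path / "s.bam"
        truth = simulate_reads(toy_config(read_length=5), toy_genome, bam)
        fwd, rev = read_bam(bam)
        assert (fwd.reference_start, fwd.reference_end) == (3, 8)
        assert (rev.reference_start, rev.reference_end) == (8, 13)
        assert not truth.reads.artifact.any()
        assert (truth.reads.regime == "truncated").all()


class TestSimulatorInvariants:
    def make_mixed(self, tmp_path, L=50, depth=3, seed=4, paired=False, **kw):
        spacings = [spacing_for_filled(f) for f in (50, 45, 80, 51, 120)] * 3
        genome = make_structured_genome(spacings, seed=seed)
        cfg = SimConfig(read_length=L, depth=depth, paired=paired, seed=seed, **kw)
        bam = tmp_path / "mix.bam"
        truth = simulate_reads(cfg, genome, bam)
        return genome, cfg, bam, truth

    def test_spans_lie_within_filled_fragments(self, tmp_path):
        genome, cfg, bam, truth = self.make_mixed(tmp_path)
        frags = [f for f in digest(genome)
                 if cfg.size_min <= f.filled_len <= cfg.size_max]
        for row in truth.reads.itertuples():
            f = frags[row.fragment]
            assert f.a + 1 <= row.start and row.end <= f.b + 3

    def test_artifact_iff_terminal_base_is_final_fill_base(self, tmp_path):
        genome, cfg, bam, truth = self.make_mixed(tmp_path)
        frags = [f for f in digest(genome)
                 if cfg.size_min <= f.filled_len <= cfg.size_max]
        for row in truth.reads.itertuples():
            f = frags[row.fragment]
            terminal_at_fill = (
                row.end == f.b + 3 if row.strand == "+" else row.start == f.a + 1
            )
            assert row.artifact == terminal_at_fill

    def test_ttg_law(self, tmp_path):
        # Default chemistry: every artifact read ends (sequencing
        # orientation) in TTG; the fill-leak regime (filled = L + 1) covers
        # a fill base but ends in T, not the TTG signature.
        genome, cfg, bam, truth = self.make_mixed(
            tmp_path, seed=8, depth=5)
        by_name = {(r.query_name, r.flag): r for r in read_bam(bam)}
        leak = truth.reads[truth.reads.covers_fill & ~truth.reads.artifact]
        assert len(leak) > 0  # the filled = L+1 fragments
        for row in truth.reads.itertuples():
            rec = by_name[(row.qname, 16 if row.strand == "-" else 0)]
            seq = rec.query_sequence
            tri = revcomp(seq[:3]) if rec.is_reverse else seq[-3:]
            if row.artifact:
                assert tri == "TTG"
            elif row.covers_fill:
                assert tri.endswith("T")

    def test_xm_characters_match_genomic_context(self, tmp_path):
        genome, cfg, bam, truth = self.make_mixed(tmp_path, depth=2,
                                                  non_cpg_level=0.3,
                                                  conversion_rate=0.98)
        seq = genome.sequences["chrS"]
        for rec in read_bam(bam):
            xm = rec.get_tag("XM")
            bottom = rec.get_tag("XG") == "GA"
            for q, r in rec.get_aligned_pairs(matches_only=True):
                c = xm[q]
                if c == ".":
                    continue
                if not bottom:
                    assert seq[r] == "C"
                    if c in "Zz":
                        assert seq[r + 1] == "G"
                    elif c in "Xx":
                        assert seq[r + 1] != "G" and seq[r + 2] == "G"
                    else:
                        assert seq[r + 1] != "G" and seq[r + 2] != "G"
                else:
                    assert seq[r] == "G"
                    if c in "Zz":
                        assert seq[r - 1] == "C"
                    elif c in "Xx":
                        assert seq[r - 1] != "C" and seq[r - 2] == "C"
                # call case reflects the stored base
                base = rec.query_sequence[q]
                if c.isupper():
                    assert base == ("G" if bottom else "C")
                else:
                    assert base == ("A" if bottom else "T")

    def test_deterministic_bam_payload(self, tmp_path):
        genome = make_structured_genome([44] * 3, seed=2)
        cfg = SimConfig(read_length=50, depth=4, seed=13)
        h = []
        for name in ("a.bam", "b.bam"):
            simulate_reads(cfg, genome, tmp_path / name)
            h.append(hashlib.md5((tmp_path / name).read_bytes()).hexdigest())
        assert h[0] == h[1]

    def test_output_is_coordinate_sorted(self, tmp_path):
        genome, cfg, bam, truth = self.make_mixed(tmp_path)
        recs = read_bam(bam)
        keys = [(r.reference_id, r.reference_start) for r in recs]
        assert keys == sorted(keys)
        with pysam.AlignmentFile(str(bam)) as fh:
            assert fh.header.to_dict()["HD"]["SO"] == "coordinate"

    def test_size_selection(self, tmp_path):
        genome = make_structured_genome(
            [spacing_for_filled(f) for f in (50, 300)], seed=1)
        cfg = SimConfig(read_length=50, depth=2, seed=1)  # default 40-220
        truth = simulate_reads(cfg, genome, tmp_path / "s.bam")
        assert set(truth.reads.fragment) == {0}

    def test_no_surviving_fragments_warns_and_writes_empty(self, tmp_path, caplog):
        genome = make_structured_genome([spacing_for_filled(300)], seed=1)
        cfg = SimConfig(read_length=50, depth=2, seed=1)
        with caplog.at_level("WARNING"):
            truth = simulate_reads(cfg, genome, tmp_path / "s.bam")
        assert len(truth.reads) == 0
        assert read_bam(tmp_path / "s.bam") == []
        assert any("size selection" in m for m in caplog.messages)

    def test_incomplete_conversion_leaves_uppercase_calls(self, tmp_path):
        genome = make_structured_genome([44] * 5, seed=3)
        cfg = SimConfig(read_length=50, depth=10, seed=3, cpg_level=0.0,
                        conversion_rate=0.5)
        simulate_reads(cfg, genome, tmp_path / "s.bam")
        xms = "".join(r.get_tag("XM") for r in read_bam(tmp_path / "s.bam"))
        assert xms.count("Z") > 0  # conversion failures read as methylated


class TestPairedEnd:
    def test_r2_geometry_and_flags(self, tmp_path, toy_genome):
        bam = tmp_path / "pe.bam"
        truth = simulate_reads(toy_config(paired=True), toy_genome, bam)
        recs = {r.flag: r for r in read_bam(bam)}
        assert set(recs) == {99, 147, 83, 163}
        # R2 of the top-strand molecule: fill bases (11, 12) trimmed
        r2_top = recs[147]
        assert (r2_top.reference_start, r2_top.reference_end) == (3, 11)
        # R2 of the bottom-strand molecule: fill bases (3, 4) trimmed
        r2_bot = recs[163]
        assert (r2_bot.reference_start, r2_bot.reference_end) == (5, 13)
        # mates share qname; template lengths are mirrored
        assert recs[99].query_name == recs[147].query_name
        assert recs[99].template_length == -recs[147].template_length
        r2_rows = truth.reads[truth.reads.mate == 2]
        assert not r2_rows.artifact.any()
        assert not r2_rows.covers_fill.any()

    def test_r2_never_covers_fill_on_mixed_genome(self, tmp_path):
        spacings = [spacing_for_filled(f) for f in (50, 30, 80, 120)]
        genome = make_structured_genome(spacings, seed=6)
        cfg = SimConfig(read_length=50, depth=2, paired=True, seed=6)
        truth = simulate_reads(cfg, genome, tmp_path / "pe.bam")
        assert not truth.reads[truth.reads.mate == 2].covers_fill.any()


class TestTwoGroups:
    def make_genome(self):
        spacings = [spacing_for_filled(f) for f in (50, 200, 100, 200) * 3]
        return make_structured_genome(spacings, seed=21)

    def test_bias_exposed_sets_disjoint_for_different_read_lengths(self, tmp_path):
        genome = self.make_genome()
        a = SimConfig(read_length=50, depth=2, seed=1)
        b = SimConfig(read_length=100, depth=2, seed=2)
        sim = simulate_two_groups(a, b, 2, genome, tmp_path)
        assert sim.bias_exposed_a and sim.bias_exposed_b
        assert sim.bias_exposed_a.isdisjoint(sim.bias_exposed_b)
        assert len(sim.bams_a) == len(sim.bams_b) == 2
        # per-sample outputs differ (independent sampling seeds)
        payloads = {p.read_bytes() for p in sim.bams_a + sim.bams_b}
        assert len(payloads) == 4

    def test_identical_configs_share_bias_sets(self, tmp_path):
        genome = self.make_genome()
        a = SimConfig(read_length=50, depth=2, seed=1)
        sim = simulate_two_groups(a, a, 1, genome, tmp_path)
        assert sim.bias_exposed_a == sim.bias_exposed_b

    def test_zero_samples_rejected(self, tmp_path):
        genome = self.make_genome()
        a = SimConfig(read_length=50, depth=2, seed=1)
        with pytest.raises(ValueError):
            simulate_two_groups(a, a, 0, genome, tmp_path)

    def test_mismatched_methylomes_rejected(self, tmp_path):
        genome = self.make_genome()
        a = SimConfig(read_length=50, depth=2, seed=1, cpg_level=0.8)
        b = SimConfig(read_length=100, depth=2, seed=2, cpg_level=0.2)
        with pytest.raises(ValueError, match="methylome"):
            simulate_two_groups(a, b, 1, genome, tmp_path)

    def test_bias_units_are_read_length_minus_two_apart(self):
        genome = self.make_genome()
        cfg = SimConfig(read_length=50, depth=1, seed=1)
        exposed = bias_exposed_units(genome, cfg)
        per_frag = {}
        for f in digest(genome):
            if f.filled_len == 50:
                per_frag[f] = {(f.chrom, f.a + 1), (f.chrom, f.b + 1)}
        assert set().union(*per_frag.values()) == exposed
        for f in per_frag:
            assert (f.b + 1) - (f.a + 1) == 50 - 2


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(read_length=4),
            dict(size_min=100, size_max=50),
            dict(cpg_level=1.5),
            dict(conversion_rate=-0.1),
            dict(depth=0),
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SimConfig(**kw)

    def test_methylome_overrides(self):
        g = ReferenceGenome({"c": "ACGTTCGA"})
        cfg = SimConfig(cpg_level=0.5, per_cpg_levels={("c", 1): 0.9})
        m = build_methylome(g, cfg)
        assert m == {("c", 1): 0.9, ("c", 5): 0.5}
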