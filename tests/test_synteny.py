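"""Alignment parsing, chaining, break detection and liftover."""

import numpy as np
import pytest

from oracles import min_chain_partition_bruteforce
from syntegrity import simulate as sim
from syntegrity import synteny
from syntegrity.synteny import AlignmentBlock, LiftoverMap


def blk(a0, a1, b0, b1, orient="+", a_chrom="A1", b_chrom="B1"):
    return AlignmentBlock(a_chrom, a0, a1, b_chrom, b0, b1, orient)


class TestReaders:
    def test_paf_reverse_strand_normalised(self, tmp_path):
        p = tmp_path / "x.paf"
        p.write_text("q1\t5000\t100\t600\t-\tt1\t9000\t2000\t2500\t480\t500\t60\n")
        (b,) = synteny.read_alignment_blocks(p, dialect="paf")
        assert b.orientation == "-"
        assert (b.a_start, b.a_end) == (100, 600)
        assert (b.b_start, b.b_end) == (2000, 2500)
        assert b.b_start < b.b_end

    def test_coords_one_based_inclusive_conversion(self, tmp_path):
        p = tmp_path / "x.coords"
        p.write_text("101\t200\t1101\t1200\t100\t100\t99.9\tA1\tB1\n")
        (b,) = synteny.read_alignment_blocks(p, dialect="coords")
        assert (b.a_start, b.a_end) == (100, 200)
        assert (b.b_start, b.b_end) == (1100, 1200)
        assert b.orientation == "+"

    def test_coords_reverse_hit(self, tmp_path):
        p = tmp_path / "x.coords"
        p.write_text("101\t200\t1200\t1101\t100\t100\t99.9\tA1\tB1\n")
        (b,) = synteny.read_alignment_blocks(p, dialect="coords")
        assert b.orientation == "-"
        assert (b.b_start, b.b_end) == (1100, 1200)

    @pytest.mark.parametrize("dialect", ["coords", "paf"])
    def test_roundtrip(self, tmp_path, dialect):
        blocks = [
            blk(0, 1000, 5000, 6000),
            blk(2000, 2600, 3000, 3600, "-"),
            blk(9000, 9800, 0, 800, a_chrom="A2", b_chrom="B2"),
        ]
        p = tmp_path / f"x.{dialect}"
        synteny.write_alignment_blocks(blocks, p, dialect=dialect)
        assert synteny.read_alignment_blocks(p, dialect=dialect) == blocks

    def test_discordant_lengths_rejected(self, tmp_path):
        p = tmp_path / "x.coords"
        p.write_text("1\t1000\t1\t500\t1000\t500\t90.0\tA1\tB1\n")
        assert synteny.read_alignment_blocks(p) == []
        assert len(synteny.read_alignment_blocks(p, reject_discordant_lengths=False)) == 1

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "x.coords"
        p.write_text("1\t100\t1\t100\t100\t100\t99\tA1\tB1\nnot\tnumbers\n")
        with pytest.raises(ValueError, match="line 2"):
            synteny.read_alignment_blocks(p)

    def test_unknown_dialect(self, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            synteny.read_alignment_blocks(tmp_path / "x", dialect="sam")


class TestChaining:
    def test_colinear_blocks_one_chain(self):
        chains = synteny.chain_blocks(
            [blk(0, 100_000, 0, 100_000), blk(150_000, 250_000, 150_000, 250_000)]
        )
        assert len(chains) == 1

    def test_orientation_split(self):
        chains = synteny.chain_blocks(
            [blk(0, 100_000, 0, 100_000), blk(100_000, 200_000, 100_000, 200_000, "-")]
        )
        assert len(chains) == 2

    def test_min_block_filter(self):
        chains = synteny.chain_blocks([blk(0, 5_000, 0, 5_000)])
        assert chains == []

    def test_chain_count_matches_bruteforce(self, rng):
        """Greedy chaining yields the optimal co-linear partition."""
        max_gap = 50_000

        def valid_pair(p, q):
            if q.b_chrom != p.b_chrom or q.orientation != p.orientation:
                return False
            if q.a_start - p.a_end > max_gap:
                return False
            if p.orientation == "+":
                return p.b_end <= q.b_start <= p.b_end + max_gap
            return p.b_start - max_gap <= q.b_end <= p.b_start

        oracle = min_chain_partition_bruteforce(valid_pair)
        for _ in range(40):
            k = rng.integers(2, 13)
            a = 0
            blocks = []
            for _i in range(k):
                a += int(rng.integers(0, 80_000))
                length = int(rng.integers(15_000, 60_000))
                b0 = int(rng.integers(0, 2_000_000))
                blocks.append(
                    blk(a, a + length, b0, b0 + length,
                        "+" if rng.random() < 0.7 else "-")
                )
                a += length
            got = synteny.chain_blocks(blocks, min_block=10_000, max_gap=max_gap)
            assert len(got) == oracle(blocks)
            assert sum(len(c.blocks) for c in got) == len(blocks)


class TestDetectBreaks:
    def _inv_blocks(self):
        return [
            blk(0, 1_000_000, 0, 1_000_000),
            blk(1_000_000, 2_000_000, 1_000_000, 2_000_000, "-"),
            blk(2_000_000, 3_000_000, 2_000_000, 3_000_000),
        ]

    def test_canonical_inversion(self):
        cands = synteny.detect_breaks(synteny.chain_blocks(self._inv_blocks()))
        assert len(cands) == 1
        c = cands[0]
        assert c.kind == "Inv"
        assert (c.a_start_bp, c.a_end_bp) == (1_000_000, 2_000_000)
        assert c.size == 1_000_000

    def test_translocation_other_chromosome(self):
        blocks = self._inv_blocks()
        blocks[1] = blk(1_000_000, 2_000_000, 4_000_000, 5_000_000, "+", b_chrom="B2")
        (c,) = synteny.detect_breaks(synteny.chain_blocks(blocks))
        assert c.kind == "Trans"
        assert c.b_chrom == "B2"

    def test_identity_alignment_no_candidates(self):
        blocks = [blk(0, 5_000_000, 0, 5_000_000), blk(0, 7_000_000, 0, 7_000_000, a_chrom="A2", b_chrom="B2")]
        assert synteny.detect_breaks(synteny.chain_blocks(blocks)) == []

    def test_sub_threshold_suppressed(self):
        blocks = [
            blk(0, 1_000_000, 0, 1_000_000),
            blk(1_000_000, 1_050_000, 1_000_000, 1_050_000, "-"),
            blk(1_050_000, 2_000_000, 1_050_000, 2_000_000),
        ]
        assert synteny.detect_breaks(synteny.chain_blocks(blocks)) == []

    def test_output_ordered_by_size_descending(self):
        plan = sim.MisassemblyPlan(
            {"c1": 20_000_000},
            (
                sim.Inversion("c1", 1_000_000, 1_400_000),
                sim.Inversion("c1", 5_000_000, 10_000_000),
                sim.Inversion("c1", 15_000_000, 16_000_000),
            ),
        )
        cands = synteny.detect_breaks(
            synteny.chain_blocks(sim.apply_misassembly(plan).to_alignment_blocks())
        )
        sizes = [c.size for c in cands]
        assert sizes == sorted(sizes, reverse=True)
        assert len(cands) == 3

    def test_planted_inversion_recovered_at_block_boundaries(self):
        plan = sim.MisassemblyPlan(
            {"c1": 20_000_000}, (sim.Inversion("c1", 7_000_000, 12_000_000),)
        )
        (c,) = synteny.detect_breaks(
            synteny.chain_blocks(sim.apply_misassembly(plan).to_alignment_blocks())
        )
        assert c.kind == "Inv"
        assert (c.a_start_bp, c.a_end_bp) == (7_000_000, 12_000_000)

    def test_symmetry_under_assembly_swap(self):
        for plan in [
            sim.MisassemblyPlan({"c1": 10_000_000}, (sim.Inversion("c1", 4_000_000, 6_000_000),)),
            sim.MisassemblyPlan(
                {"c1": 10_000_000, "c2": 8_000_000},
                (sim.Translocation("c1", 3_000_000, 3_500_000, "c2", 4_000_000),),
            ),
        ]:
            blocks = sim.apply_misassembly(plan).to_alignment_blocks()
            fwd = synteny.detect_breaks(synteny.chain_blocks(blocks))
            rev = synteny.detect_breaks(
                synteny.chain_blocks(synteny.swap_assemblies(blocks))
            )
            assert [c.kind for c in fwd] == [c.kind for c in rev]
            assert {(c.a_start_bp, c.a_end_bp) for c in rev} == {
                (c.b_start_bp, c.b_end_bp) for c in fwd
            } or len(fwd) == len(rev) == 1


class TestLiftover:
    def test_forward_offset(self):
        lom = LiftoverMap([blk(100, 200, 1100, 1200)])
        assert lom.lift("A1", 150) == ("B1", 1150)

    def test_reverse_reflection(self):
        lom = LiftoverMap([blk(100, 200, 1100, 1200, "-")])
        assert lom.lift("A1", 150) == ("B1", 1149)

    def test_unmapped_gap_returns_none(self):
        lom = LiftoverMap([blk(100, 200, 1100, 1200)])
        assert lom.lift("A1", 250) is None
        assert lom.lift("A9", 150) is None

    def test_roundtrip_identity(self, rng):
        plan = sim.MisassemblyPlan(
            {"c1": 10_000_000, "c2": 6_000_000},
            (
                sim.Inversion("c1", 2_000_000, 5_000_000),
                sim.Translocation("c1", 6_000_000, 6_500_000, "c2", 1_000_000),
            ),
        )
        blocks = sim.apply_misassembly(plan).to_alignment_blocks()
        fwd = LiftoverMap(blocks)
        back = fwd.inverse()
        for _ in range(1000):
            chrom = "c1" if rng.random() < 0.6 else "c2"
            pos = int(rng.integers(0, 6_000_000))
            lifted = fwd.lift(chrom, pos)
            assert lifted is not None
            assert back.lift(*lifted) == (chrom, pos)


class TestDotplot:
    def test_single_forward_block(self):
        df = synteny.export_dotplot([blk(0, 1_000_000, 0, 1_000_000)])
        assert len(df) == 1
        assert df.iloc[0]["orientation"] == "+"
        assert df.iloc[0]["a_mid_mb"] == pytest.approx(0.5)

    def test_empty_input(self, tmp_path):
        df = synteny.export_dotplot([], tsv_path=tmp_path / "d.tsv")
        assert df.empty

    def test_planted_inversion_anti_diagonal(self):
        plan = sim.MisassemblyPlan(
            {"c1": 10_000_000}, (sim.Inversion("c1", 4_000_000, 6_000_000),)
        )
        df = synteny.export_dotplot(sim.apply_misassembly(plan).to_alignment_blocks())
        neg = df[df["orientation"] == "-"]
        assert len(neg) == 1
        assert 4.0 <= neg.iloc[0]["a_mid_mb"] <= 6.0
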