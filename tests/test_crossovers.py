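"""Informative-site selection and minimum-recombinant inference."""

import numpy as np
import pytest
from intervaltree import IntervalTree

from conftest import call, make_vcf
from oracles import min_crossovers_bruteforce
from syntegrity import crossovers as xo
from syntegrity.synteny import BreakpointCandidate


def matrix(M, positions=None, role="paternal", ids=None):
    M = np.asarray(M, dtype=np.uint8)
    m, n = M.shape
    return xo.InheritanceMatrix(
        parent_role=role,
        parent_id="SIRE",
        chrom="chr1",
        offspring_ids=tuple(ids or (f"K{j}" for j in range(n))),
        positions=np.asarray(positions if positions is not None else np.arange(m) * 10_000),
        M=M,
    )


class TestSelectInformativeSites:
    SAMPLES = ["SIRE", "DAM1", "DAM2", "KID1", "KID2", "KID3"]

    def _records(self):
        passing = [call("0/1"), call("0/0"), call("1/1"),
                   call("0/1"), call("0/1"), call("1/1")]
        return [
            ("chr1", 1000, "A", "C", 200.0, passing),                       # keep
            ("chr1", 2000, "A", "C", 40.0, passing),                        # QUAL <= 50
            ("chr1", 3000, "A", "C", 200.0,
             passing[:3] + [call("0/1", dp=14)] + passing[4:]),             # depth 14 < 15
            ("chr1", 4000, "A", "C", 200.0,
             passing[:3] + [call("0/1", gq=39)] + passing[4:]),             # GQ < 40
            ("chr1", 5000, "A", "C", 200.0,
             passing[:3] + [call("0/1", dp=20, ad=(16, 4))] + passing[4:]), # AB 0.20
            ("chr1", 6000, "A", "C", 200.0,
             passing[:3] + ["./.:30:90:15,15"] + passing[4:]),              # missing call
            ("chr1", 7000, "A", "C", 200.0,
             [call("0/0")] + passing[1:]),                                  # sire not het
            ("chr1", 8000, "A", "C", 200.0,
             passing[:1] + [call("0/1")] + passing[2:]),                    # dam not hom
            ("chr1", 9000, "A", "CT", 200.0, passing),                      # not a SNP
            ("chr1", 50_000, "A", "C", 200.0, passing),                     # in excluded region
            ("chr1", 11_000, "A", "C", 200.0,
             passing[:2] + [call("1/1", dp=30, ad=(4, 26))] + passing[3:]), # hom AB 0.133
        ]

    def test_planted_pass_fail_enumeration(self, tmp_path, tiny_pedigree):
        vcf = make_vcf(tmp_path / "t.vcf", self.SAMPLES, self._records())
        filt = xo.GenotypeCallFilter(
            exclude_regions={"chr1": IntervalTree.from_tuples([(40_000, 60_000)])}
        )
        got = xo.select_informative_sites(vcf, tiny_pedigree, filt, role="paternal")
        assert list(got["chr1"]["pos"]) == [999]  # only the first site survives

    def test_maternal_pattern(self, tmp_path, tiny_pedigree):
        rec = [("chr1", 1000, "A", "C", 200.0,
                [call("1/1"), call("0/1"), call("0/1"),
                 call("1/1"), call("0/1"), call("1/1")])]
        vcf = make_vcf(tmp_path / "t.vcf", self.SAMPLES, rec)
        got = xo.select_informative_sites(vcf, tiny_pedigree, role="maternal")
        assert len(got["chr1"]) == 1
        assert xo.select_informative_sites(vcf, tiny_pedigree, role="paternal") == {}

    def test_missing_sample_named(self, tmp_path, tiny_pedigree):
        vcf = make_vcf(tmp_path / "t.vcf", self.SAMPLES[:-1], [])
        with pytest.raises(KeyError, match="KID3"):
            xo.select_informative_sites(vcf, tiny_pedigree)

    def test_missing_ad_field_errors(self, tmp_path, tiny_pedigree):
        p = tmp_path / "noad.vcf"
        with open(p, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n##contig=<ID=chr1,length=10000000>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n')
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="q">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.SAMPLES) + "\n")
            cells = ["0/1:30:90", "0/0:30:90", "1/1:30:90"] + ["0/1:30:90"] * 3
            fh.write("chr1\t1000\t.\tA\tC\t200\t.\t.\tGT:DP:GQ\t" + "\t".join(cells) + "\n")
        with pytest.raises(xo.MissingFieldError, match="AD"):
            xo.select_informative_sites(p, tiny_pedigree)

    def test_filter_field_constraint(self):
        with pytest.raises(ValueError):
            xo.GenotypeCallFilter(het_ab_min=0.05, hom_ab_max=0.07)


class TestBuildInheritanceMatrices:
    def _markers(self, rows, tiny_pedigree):
        import pandas as pd

        cols = ["pos", "SIRE", "DAM1", "DAM2", "KID1", "KID2", "KID3"]
        return {"chr1": pd.DataFrame(rows, columns=cols)}

    def test_mendelian_subtraction(self, tiny_pedigree):
        # sire 0/1; dams hom: DAM1=0/0, DAM2=1/1
        rows = [
            (100, 1, 0, 2, 1, 0, 1),   # KID1 het->1, KID2 hom ref->0, KID3 (dam 1/1)->0
            (200, 1, 2, 0, 2, 1, 1),   # dam1 1/1: KID1 2-1=1, KID2 1-1=0; dam2 0/0: KID3 1
        ]
        (mat,) = xo.build_inheritance_matrices(
            self._markers(rows, tiny_pedigree), tiny_pedigree, role="paternal"
        )
        assert mat.M.tolist() == [[1, 0, 0], [1, 0, 1]]

    def test_mendelian_inconsistency_dropped(self, tiny_pedigree):
        rows = [
            (100, 1, 0, 2, 1, 0, 1),
            (200, 1, 0, 2, 2, 0, 1),   # KID1 1/1 with dam 0/0 -> impossible
        ]
        (mat,) = xo.build_inheritance_matrices(
            self._markers(rows, tiny_pedigree), tiny_pedigree, role="paternal"
        )
        assert len(mat.positions) == 1
        assert mat.n_mendel_dropped == 1

    def test_maternal_one_matrix_per_dam(self, tiny_pedigree):
        rows = [(100, 0, 1, 1, 0, 1, 1), (200, 2, 1, 1, 1, 2, 1)]
        mats = xo.build_inheritance_matrices(
            self._markers(rows, tiny_pedigree), tiny_pedigree, role="maternal"
        )
        assert {m.parent_id for m in mats} == {"DAM1", "DAM2"}
        by_dam = {m.parent_id: m for m in mats}
        assert by_dam["DAM1"].offspring_ids == ("KID1", "KID2")
        assert by_dam["DAM1"].M.tolist() == [[0, 1], [0, 1]]
        assert by_dam["DAM2"].M.tolist() == [[1], [0]]


class TestMinCrossovers:
    def test_identical_rows_zero(self):
        total, events = xo.min_crossovers(matrix([[0, 1, 0], [0, 1, 0]]))
        assert total == 0 and events == []

    def test_complement_rows_zero(self):
        """A full phase flip is free: exact complements imply no crossover."""
        total, _ = xo.min_crossovers(matrix([[0] * 9, [1] * 9]))
        assert total == 0

    def test_single_switch(self):
        total, events = xo.min_crossovers(
            matrix([[0, 0, 0], [1, 0, 0]], positions=[100, 900])
        )
        assert total == 1
        assert events[0].meiosis_id == ("K0", "paternal")
        assert (events[0].left, events[0].right) == (100, 900)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            xo.min_crossovers(matrix(np.zeros((1, 3))))
        with pytest.raises(ValueError):
            xo.min_crossovers(matrix(np.zeros((3, 0))))

    def test_tie_marked_ambiguous(self):
        _, events = xo.min_crossovers(matrix([[0, 0], [0, 1]]))
        assert len(events) == 1 and events[0].ambiguous

    def test_matches_exhaustive_phase_enumeration(self, rng):
        for _ in range(60):
            m = int(rng.integers(2, 9))
            n = int(rng.integers(1, 7))
            M = rng.integers(0, 2, size=(m, n)).astype(np.uint8)
            total, events = xo.min_crossovers(matrix(M))
            assert total == min_crossovers_bruteforce(M)
            assert total == len(events)

    def test_phase_flip_invariance(self, rng):
        for _ in range(60):
            M = rng.integers(0, 2, size=(6, 5)).astype(np.uint8)
            i = int(rng.integers(0, 6))
            flipped = M.copy()
            flipped[i] ^= 1
            assert xo.min_crossovers(matrix(M))[0] == xo.min_crossovers(matrix(flipped))[0]

    def test_column_permutation_invariance(self, rng):
        for _ in range(60):
            M = rng.integers(0, 2, size=(6, 5)).astype(np.uint8)
            perm = rng.permutation(5)
            assert (
                xo.min_crossovers(matrix(M))[0]
                == xo.min_crossovers(matrix(M[:, perm]))[0]
            )


class TestSmoothing:
    def test_isolated_flip_removed(self):
        M = np.zeros((7, 3), dtype=np.uint8)
        M[3, 0] = 1  # one-marker excursion in offspring 0
        total, events = xo.min_crossovers(matrix(M))
        assert total == 2
        assert xo.smooth_gene_conversions(events, matrix(M)) == []

    def test_supported_crossover_retained(self):
        M = np.zeros((60, 3), dtype=np.uint8)
        M[10:, 1] = 1  # switch supported by 50 downstream markers
        total, events = xo.min_crossovers(matrix(M))
        smoothed = xo.smooth_gene_conversions(events, matrix(M))
        assert len(smoothed) == 1
        assert smoothed[0].meiosis_id[0] == "K1"

    def test_terminal_excursion_kept(self):
        M = np.zeros((6, 3), dtype=np.uint8)
        M[-1, 2] = 1  # last marker: switch has no partner
        _, events = xo.min_crossovers(matrix(M))
        assert len(xo.smooth_gene_conversions(events, matrix(M))) == 1

    def test_error_robustness_simulation(self, rng):
        """With 0.2% genotype error at 1 marker/10 kb, the smoothed
        per-meiosis crossover count stays within +-1 of the planted truth
        for >=95% of meioses over 200 replicates."""
        ok = tries = 0
        for _ in range(200):
            m, n = 300, 9  # 3 Mb at 1 marker / 10 kb
            positions = np.sort(rng.choice(3_000_000, size=m, replace=False))
            truth = np.zeros((m, n), dtype=np.uint8)
            planted = np.zeros(n, dtype=int)
            for j in range(n):
                k = rng.poisson(0.5 * 3)  # 0.5 events/meiosis/Mb
                xs = np.sort(rng.integers(0, 3_000_000, size=k))
                states = np.searchsorted(xs, positions, side="right") % 2
                planted[j] = int((np.diff(states) != 0).sum())
                truth[:, j] = states
            noisy = truth ^ (rng.random((m, n)) < 0.002)
            mat = matrix(noisy.astype(np.uint8), positions=positions)
            _, events = xo.min_crossovers(mat)
            smoothed = xo.smooth_gene_conversions(events, mat)
            counts = np.zeros(n, dtype=int)
            for ev in smoothed:
                counts[int(ev.meiosis_id[0][1:])] += 1
            ok += int((np.abs(counts - planted) <= 1).sum())
            tries += n
        assert ok / tries >= 0.95


class TestClusters:
    def _ev(self, left, right, who="K0", role="paternal"):
        return xo.CrossoverEvent(meiosis_id=(who, role), chrom="chr1", left=left, right=right)

    def test_three_shared_interval_events_flagged(self):
        events = [self._ev(100_000, 110_000, w) for w in ("K0", "K1", "K2")]
        (flag,) = xo.detect_crossover_clusters(events)
        assert flag.n_events == 3
        assert (flag.start, flag.end) == (100_000, 110_000)

    def test_two_events_below_threshold(self):
        events = [self._ev(100_000, 110_000, w) for w in ("K0", "K1")]
        assert xo.detect_crossover_clusters(events) == []

    def test_merge_window_bridges_nearby_events(self):
        events = [
            self._ev(100_000, 110_000, "K0"),
            self._ev(130_000, 140_000, "K1"),  # 20 kb away < 50 kb padding sum
            self._ev(150_000, 160_000, "K2"),
        ]
        (flag,) = xo.detect_crossover_clusters(events, merge_window=50_000)
        assert flag.n_events == 3

    def test_distant_events_not_merged(self):
        events = [
            self._ev(100_000, 110_000, "K0"),
            self._ev(500_000, 510_000, "K1"),
            self._ev(900_000, 910_000, "K2"),
        ]
        assert xo.detect_crossover_clusters(events) == []


class TestLinkageEvidence:
    def _cand(self, start=1_000_000, end=2_000_000, chrom="chr1"):
        return BreakpointCandidate("Inv", chrom, start, end, chrom, start, end)

    def _flag(self, start, end, chrom="chr1"):
        return xo.CrossoverClusterFlag(chrom=chrom, start=start, end=end, n_events=3, meioses=())

    def test_both_breakpoints_flagged(self):
        flags = [self._flag(990_000, 1_010_000), self._flag(1_990_000, 2_010_000)]
        labels = xo.linkage_evidence(flags, [self._cand()])
        assert list(labels.values()) == ["start+end"]

    def test_no_flags_within_window(self):
        labels = xo.linkage_evidence([self._flag(1_400_000, 1_500_000)], [self._cand()])
        assert list(labels.values()) == ["no"]

    def test_one_sided_labels(self):
        assert list(
            xo.linkage_evidence([self._flag(960_000, 980_000)], [self._cand()]).values()
        ) == ["start"]
        assert list(
            xo.linkage_evidence([self._flag(2_020_000, 2_040_000)], [self._cand()]).values()
        ) == ["end"]

    def test_coordinate_mismatch_raises(self):
        with pytest.raises(xo.CoordinateSystemError):
            xo.linkage_evidence(
                [self._flag(0, 10_000, chrom="alt7")], [self._cand(chrom="chr1")]
            )
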