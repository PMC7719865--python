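"""Synthetic inputs for the misassembly-validation pipeline.

The generator builds a chromosome-scale *truth* genome and an *alt*
assembly derived from it by planted inversion/translocation misjoins,
then emulates every downstream data type the pipeline consumes:

* perfect-aligner alignment blocks between alt and truth (the exact
  chains an aligner would produce, so break detection can be tested
  against the plan);
* a pedigree VCF (sire, two dams, their offspring) with Poisson
  crossovers simulated on the *truth* genome but records sorted by
  *alt* coordinates - which is precisely how a misjoin turns ordinary
  recombination into an apparent pile-up of crossovers at the junction;
* a population rho track with gamma background and spikes at misjoin
  junctions;
* random repeat-exclusion BEDs.

All randomness flows through one ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crossovers import PedigreeSpec
from .ldscan import RhoTrack
from .synteny import AlignmentBlock

__all__ = [
    "Inversion",
    "Translocation",
    "MisassemblyPlan",
    "CoordinateMap",
    "SimulationConfig",
    "default_pedigree",
    "apply_misassembly",
    "simulate_pedigree_vcf",
    "expected_switches",
    "simulate_rho_track",
    "simulate_exclusion_bed",
    "write_bed",
    "SimTruth",
]


@dataclass(frozen=True)
class Inversion:
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class Translocation:
    chrom: str
    start: int
    end: int
    dest_chrom: str
    dest_pos: int


@dataclass(frozen=True)
class MisassemblyPlan:
    """Truth-genome geometry plus an ordered list of misjoin operations.

    Operation intervals must lie within their chromosome and be pairwise
    non-overlapping in truth space; a translocation's insertion point
    must not fall inside any operation interval.  Sub-threshold (<100
    kb) operations are allowed - they are useful as negative controls.
    """

    chrom_lengths: dict[str, int]
    operations: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "operations", tuple(self.operations))
        intervals: dict[str, list[tuple[int, int]]] = {}
        for op in self.operations:
            L = self.chrom_lengths.get(op.chrom)
            if L is None:
                raise ValueError(f"operation on unknown chromosome {op.chrom!r}")
            if not (0 <= op.start < op.end <= L):
                raise ValueError(f"operation interval out of bounds: {op}")
            intervals.setdefault(op.chrom, []).append((op.start, op.end))
            if isinstance(op, Translocation):
                Ld = self.chrom_lengths.get(op.dest_chrom)
                if Ld is None or not (0 <= op.dest_pos <= Ld):
                    raise ValueError(f"translocation destination out of bounds: {op}")
        for chrom, ivs in intervals.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping operations on {chrom}: "
                        f"[{s1},{e1}) and [{s2},{e2})"
                    )
        for op in self.operations:
            if isinstance(op, Translocation):
                for s, e in intervals.get(op.dest_chrom, []):
                    if s < op.dest_pos < e:
                        raise ValueError(
                            f"translocation destination {op.dest_pos} falls inside "
                            f"another operation interval on {op.dest_chrom}"
                        )


@dataclass(frozen=True)
class _Segment:
    truth_chrom: str
    t_start: int
    t_end: int
    alt_chrom: str
    a_start: int
    a_end: int
    orientation: str  # "+" or "-"


@dataclass(frozen=True)
class CoordinateMap:
    """Piecewise bijection between truth and alt coordinates."""

    segments: tuple[_Segment, ...]
    truth_lengths: dict[str, int]

    @property
    def alt_lengths(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.segments:
            out[s.alt_chrom] = max(out.get(s.alt_chrom, 0), s.a_end)
        return out

    def truth_to_alt(self, chrom: str, pos: int) -> tuple[str, int]:
        for s in self.segments:
            if s.truth_chrom == chrom and s.t_start <= pos < s.t_end:
                off = pos - s.t_start
                if s.orientation == "+":
                    return s.alt_chrom, s.a_start + off
                return s.alt_chrom, s.a_end - 1 - off
        raise KeyError(f"truth position {chrom}:{pos} outside the map")

    def alt_to_truth(self, chrom: str, pos: int) -> tuple[str, int]:
        for s in self.segments:
            if s.alt_chrom == chrom and s.a_start <= pos < s.a_end:
                off = pos - s.a_start
                if s.orientation == "+":
                    return s.truth_chrom, s.t_start + off
                return s.truth_chrom, s.t_end - 1 - off
        raise KeyError(f"alt position {chrom}:{pos} outside the map")

    def to_alignment_blocks(self) -> list[AlignmentBlock]:
        """Blocks with the alt assembly as A and the truth genome as B."""
        return [
            AlignmentBlock(
                a_chrom=s.alt_chrom, a_start=s.a_start, a_end=s.a_end,
                b_chrom=s.truth_chrom, b_start=s.t_start, b_end=s.t_end,
                orientation=s.orientation,
            )
            for s in self.segments
        ]

    def breakpoints(self) -> list[tuple[str, int]]:
        """Alt-coordinate positions of junctions that break truth adjacency."""
        by_alt: dict[str, list[_Segment]] = {}
        for s in self.segments:
            by_alt.setdefault(s.alt_chrom, []).append(s)
        out = []
        for chrom in sorted(by_alt):
            segs = sorted(by_alt[chrom], key=lambda s: s.a_start)
            for s1, s2 in zip(segs, segs[1:]):
                contiguous = (
                    s1.truth_chrom == s2.truth_chrom
                    and s1.orientation == s2.orientation
                    and (
                        s1.t_end == s2.t_start
                        if s1.orientation == "+"
                        else s2.t_end == s1.t_start
                    )
                )
                if not contiguous:
                    out.append((chrom, s2.a_start))
        return out


def apply_misassembly(plan: MisassemblyPlan) -> CoordinateMap:
    """Realise a plan as the truth<->alt coordinate bijection.

    The alt assembly reuses the truth chromosome names (as two releases
    of the same genome would).  Emitted alignment blocks are exactly the
    chains a perfect aligner would find.
    """
    # ordered pieces composing each alt chromosome, in truth coordinates
    items: dict[str, list[tuple[str, int, int, str]]] = {}
    excised: dict[str, list[tuple[int, int]]] = {}
    flipped: dict[str, list[tuple[int, int]]] = {}
    for op in plan.operations:
        if isinstance(op, Translocation):
            excised.setdefault(op.chrom, []).append((op.start, op.end))
        elif isinstance(op, Inversion):
            flipped.setdefault(op.chrom, []).append((op.start, op.end))
        else:
            raise TypeError(f"unknown operation {op!r}")
    for chrom, L in plan.chrom_lengths.items():
        cuts = {0, L}
        for s, e in excised.get(chrom, []) + flipped.get(chrom, []):
            cuts.update((s, e))
        bounds = sorted(cuts)
        pieces = []
        for s, e in zip(bounds, bounds[1:]):
            if (s, e) in excised.get(chrom, []):
                continue
            orient = "-" if (s, e) in flipped.get(chrom, []) else "+"
            pieces.append((chrom, s, e, orient))
        items[chrom] = pieces
    for op in plan.operations:
        if not isinstance(op, Translocation):
            continue
        dest = items[op.dest_chrom]
        at = len(dest)
        for i, (pc, ps, pe, po) in enumerate(dest):
            if pc != op.dest_chrom:
                continue
            if ps < op.dest_pos < pe:
                dest[i : i + 1] = [
                    (pc, ps, op.dest_pos, po),
                    (pc, op.dest_pos, pe, po),
                ]
                at = i + 1
                break
            if op.dest_pos <= ps:
                at = i
                break
        dest.insert(at, (op.chrom, op.start, op.end, "+"))
    segments: list[_Segment] = []
    for chrom in plan.chrom_lengths:
        offset = 0
        for pc, ps, pe, po in items[chrom]:
            segments.append(
                _Segment(
                    truth_chrom=pc, t_start=ps, t_end=pe,
                    alt_chrom=chrom, a_start=offset, a_end=offset + (pe - ps),
                    orientation=po,
                )
            )
            offset += pe - ps
    return CoordinateMap(segments=tuple(segments), truth_lengths=dict(plan.chrom_lengths))


# ---------------------------------------------------------------------------
# pedigree genotypes
# ---------------------------------------------------------------------------

def default_pedigree(n_per_dam: tuple[int, int] = (5, 4)) -> PedigreeSpec:
    """A sire x two-dam half-sib design (default 9 offspring, 5 + 4)."""
    offspring = []
    for d, n in enumerate(n_per_dam):
        dam = ("9841", "12242")[d]
        offspring.extend((f"O{d + 1}{k + 1}", dam) for k in range(n))
    return PedigreeSpec(
        sire_id="10173", dam_ids=("9841", "12242"), offspring=tuple(offspring)
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Nuisance parameters of the synthetic study.

    crossover_rate is in events per meiosis per Mb.  The default (0.5)
    deliberately exaggerates per-bp recombination so that a planted
    multi-megabase misjoin in a ~10 Mb toy genome carries an appreciable
    probability of an odd number of crossovers across it per meiosis -
    the signal the crossover-cluster test keys on; the realistic
    mammalian scale (~0.01/Mb, i.e. ~1 cM/Mb) applies to full-size
    chromosomes and is what null-calibration runs use.
    """

    seed: int
    n_offspring_per_dam: tuple[int, int] = (5, 4)
    crossover_rate: float = 0.5
    marker_density: float = 1e-4
    genotype_error_rate: float = 0.001
    depth_mean: float = 30.0
    depth_dispersion: float = 20.0
    rho_shape: float = 0.5
    rho_scale: float = 0.02
    rho_spike: float = 0.5
    rho_spike_width: int = 5_000
    rho_interval: int = 2_000

    def __post_init__(self) -> None:
        for name in (
            "crossover_rate", "marker_density", "genotype_error_rate",
            "depth_mean", "depth_dispersion", "rho_shape", "rho_scale",
            "rho_spike",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated pedigree VCF."""

    vcf_path: str
    # (sample_id, role) -> list of (truth_chrom, position)
    crossovers: dict[tuple[str, str], list[tuple[str, int]]]
    marker_positions: dict[str, np.ndarray]  # truth chrom -> positions
    marker_roles: dict[str, np.ndarray]  # truth chrom -> "paternal"/"maternal"
    n_planted_errors: int


def expected_switches(
    crossovers: list[tuple[str, int]], chrom: str, marker_positions: np.ndarray
) -> int:
    """Observable switch count: adjacent marker pairs with odd crossover
    parity between them (crossovers outside the marker span, or in even
    numbers within one interval, are invisible to any method)."""
    xo = np.sort(np.array([p for c, p in crossovers if c == chrom], dtype=np.int64))
    if len(marker_positions) < 2:
        return 0
    counts = np.searchsorted(xo, marker_positions, side="right")
    return int((np.diff(counts) % 2 == 1).sum())


def _transmitted_hap(
    rng: np.random.Generator, rate_per_mb: float, L: int, positions: np.ndarray
) -> tuple[np.ndarray, list[int]]:
    """Haplotype index (0/1) transmitted at each position for one meiosis."""
    k = rng.poisson(rate_per_mb * L / 1e6)
    xo = np.sort(rng.integers(0, L, size=k))
    start = int(rng.integers(0, 2))
    haps = (start + np.searchsorted(xo, positions, side="right")) % 2
    return haps.astype(np.int8), [int(x) for x in xo]


def simulate_pedigree_vcf(
    cmap: CoordinateMap,
    config: SimulationConfig,
    pedigree: PedigreeSpec | None = None,
    out_path="pedigree.vcf",
    rng: np.random.Generator | None = None,
) -> SimTruth:
    """Simulate pedigree genotypes on the truth genome, emit them on alt.

    Markers are placed uniformly at ``marker_density`` and alternate
    between paternal-informative (sire heterozygous, dams homozygous)
    and maternal-informative (sire homozygous, dams heterozygous)
    configurations - informativeness is imposed by construction.
    Meioses carry Poisson(rate x length) crossovers at uniform *truth*
    positions; offspring genotypes are composed Mendelianly; genotyping
    errors flip one allele of a call at ``genotype_error_rate``.
    DP/GQ/AD/QUAL are drawn so the hard call filters are exercised
    (errors receive depressed GQ).  Records are sorted by *alt*
    coordinates, so truth-space crossovers become apparent clusters at
    misjoin junctions.
    """
    pedigree = pedigree or default_pedigree(config.n_offspring_per_dam)
    rng = rng if rng is not None else config.rng()
    samples = [pedigree.sire_id, *pedigree.dam_ids, *pedigree.offspring_ids]
    dam_index = {d: i for i, d in enumerate(pedigree.dam_ids)}

    crossovers: dict[tuple[str, str], list[tuple[str, int]]] = {}
    marker_positions: dict[str, np.ndarray] = {}
    marker_roles: dict[str, np.ndarray] = {}
    records = []  # (alt_chrom, alt_pos, qual, genotypes, dp, gq, ad)
    n_errors = 0

    for chrom, L in cmap.truth_lengths.items():
        n = int(round(L * config.marker_density))
        if n < 1:
            continue
        pos = np.unique(rng.integers(0, L, size=n))
        n = len(pos)
        roles = np.where(np.arange(n) % 2 == 0, "paternal", "maternal")
        marker_positions[chrom] = pos
        marker_roles[chrom] = roles
        pat = roles == "paternal"

        # parental haplotypes: focal parent het (random phase), other hom
        sire_h0 = rng.integers(0, 2, size=n)
        sire_h1 = np.where(pat, 1 - sire_h0, sire_h0)  # het at paternal sites
        dam_h0 = np.empty((2, n), dtype=np.int64)
        dam_h1 = np.empty((2, n), dtype=np.int64)
        for d in range(2):
            h = rng.integers(0, 2, size=n)
            dam_h0[d] = h
            dam_h1[d] = np.where(pat, h, 1 - h)  # het at maternal sites

        sire_gt = sire_h0 + sire_h1
        dam_gt = dam_h0 + dam_h1

        genos = np.empty((len(samples), n), dtype=np.int64)
        genos[0] = sire_gt
        genos[1] = dam_gt[0]
        genos[2] = dam_gt[1]
        for j, (off_id, dam_id) in enumerate(pedigree.offspring):
            hp, xo_p = _transmitted_hap(rng, config.crossover_rate, L, pos)
            hm, xo_m = _transmitted_hap(rng, config.crossover_rate, L, pos)
            crossovers.setdefault((off_id, "paternal"), []).extend(
                (chrom, x) for x in xo_p
            )
            crossovers.setdefault((off_id, "maternal"), []).extend(
                (chrom, x) for x in xo_m
            )
            d = dam_index[dam_id]
            t_sire = np.where(hp == 0, sire_h0, sire_h1)
            t_dam = np.where(hm == 0, dam_h0[d], dam_h1[d])
            genos[3 + j] = t_sire + t_dam

        # genotyping errors: flip one allele of the call
        err = rng.random((len(samples), n)) < config.genotype_error_rate
        n_errors += int(err.sum())
        if err.any():
            up = rng.random((len(samples), n)) < 0.5
            g = genos
            genos = np.where(err & (g == 0), 1, g)
            genos = np.where(err & (g == 2), 1, genos)
            genos = np.where(err & (g == 1), np.where(up, 0, 2), genos)

        # per-call quality model
        nb_n = config.depth_dispersion
        nb_p = nb_n / (nb_n + config.depth_mean)
        dp = rng.negative_binomial(nb_n, nb_p, size=(len(samples), n))
        gq = rng.integers(60, 100, size=(len(samples), n))
        gq = np.where(err, rng.integers(10, 61, size=gq.shape), gq)
        alt_frac = np.where(genos == 1, 0.5, np.where(genos == 2, 0.98, 0.02))
        ad_alt = rng.binomial(dp, alt_frac)
        qual = np.round(rng.uniform(100, 1000, size=n), 1)

        alt_coords = [cmap.truth_to_alt(chrom, int(p)) for p in pos]
        for i in range(n):
            records.append(
                (
                    alt_coords[i][0], alt_coords[i][1], qual[i],
                    genos[:, i], dp[:, i], gq[:, i], ad_alt[:, i],
                )
            )

    records.sort(key=lambda r: (r[0], r[1]))
    _write_vcf(out_path, samples, cmap.alt_lengths, records)
    return SimTruth(
        vcf_path=str(out_path),
        crossovers=crossovers,
        marker_positions=marker_positions,
        marker_roles=marker_roles,
        n_planted_errors=n_errors,
    )


_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def _write_vcf(path, samples, contig_lengths, records) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, L in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={L}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for chrom, pos, qual, genos, dp, gq, ad_alt in records:
            cells = [
                f"{_GT[int(g)]}:{int(d)}:{int(q)}:{int(d) - int(a)},{int(a)}"
                for g, d, q, a in zip(genos, dp, gq, ad_alt)
            ]
            fh.write(
                f"{chrom}\t{pos + 1}\t.\tA\tC\t{qual}\t.\t.\tGT:DP:GQ:AD\t"
                + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# rho track and exclusion BED
# ---------------------------------------------------------------------------

def simulate_rho_track(
    cmap: CoordinateMap,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[RhoTrack, list[tuple[str, int]]]:
    """Gamma background rho/bp per tile, plus spikes at misjoin junctions.

    Returns the track (alt coordinates) and the list of spiked
    junctions.  With ``rho_spike == 0`` the track is pure background.
    """
    rng = rng if rng is not None else config.rng()
    rows = []
    spikes = cmap.breakpoints() if config.rho_spike > 0 else []
    spike_by_chrom: dict[str, list[int]] = {}
    for chrom, p in spikes:
        spike_by_chrom.setdefault(chrom, []).append(p)
    for chrom, L in sorted(cmap.alt_lengths.items()):
        starts = np.arange(0, L, config.rho_interval)
        ends = np.minimum(starts + config.rho_interval, L)
        rho = rng.gamma(config.rho_shape, config.rho_scale, size=len(starts))
        half = config.rho_spike_width // 2
        for p in spike_by_chrom.get(chrom, []):
            hit = (ends > p - half) & (starts < p + half)
            rho[hit] += config.rho_spike
        rows.extend(zip([chrom] * len(starts), starts, ends, rho))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "rho_per_bp"])
    return RhoTrack(df, provenance="simulated"), spikes


def simulate_exclusion_bed(
    chrom_lengths: dict[str, int],
    fraction: float,
    rng: np.random.Generator,
    tile: int = 5_000,
) -> pd.DataFrame:
    """Random non-overlapping intervals covering ~``fraction`` of the genome."""
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    rows = []
    for chrom, L in sorted(chrom_lengths.items()):
        starts = np.arange(0, L, tile)
        keep = rng.random(len(starts)) < fraction
        for s in starts[keep]:
            rows.append((chrom, int(s), int(min(s + tile, L))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)
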