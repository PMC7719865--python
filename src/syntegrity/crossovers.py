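"""Minimum-recombinant crossover inference in a two-dam half-sib pedigree.

The design is a sire, two dams and their offspring, all genotyped.  At
sites where the focal parent is heterozygous and the other parent(s)
homozygous, the allele transmitted by the focal parent is determined by
Mendelian subtraction, giving an ordered markers x offspring binary
inheritance matrix per chromosome.  Because the focal parent's
haplotype phase is unknown, crossovers are counted by the minimum
number of switches consistent with the matrix: for each adjacent marker
pair the contribution is min(d, n - d), where d is the Hamming distance
between the two rows and n the number of offspring (complementing a row
is a free phase choice).

Loci where at least ``cluster_min`` (default 3) of the pooled meioses
appear to recombine in the same place are flagged: genuine recombination
is far too rare for that, so such pile-ups indicate an assembly misjoin
rather than biology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .synteny import BreakpointCandidate

__all__ = [
    "PedigreeSpec",
    "GenotypeCallFilter",
    "InheritanceMatrix",
    "CrossoverEvent",
    "CrossoverClusterFlag",
    "read_pedigree_tsv",
    "read_bed_intervals",
    "select_informative_sites",
    "build_inheritance_matrices",
    "min_crossovers",
    "smooth_gene_conversions",
    "detect_crossover_clusters",
    "linkage_evidence",
    "write_events_bed",
    "write_flags_bed",
    "write_painting_tsv",
]

SUPPORT_LABELS = ("start", "end", "start+end", "no", "unknown")


@dataclass(frozen=True)
class PedigreeSpec:
    """One sire, two dams, and offspring assigned to a dam each."""

    sire_id: str
    dam_ids: tuple[str, str]
    offspring: tuple[tuple[str, str], ...]  # (offspring_id, dam_id)

    def __post_init__(self) -> None:
        ids = [self.sire_id, *self.dam_ids, *(o for o, _ in self.offspring)]
        if len(set(ids)) != len(ids):
            raise ValueError("pedigree sample ids are not unique")
        for off, dam in self.offspring:
            if dam not in self.dam_ids:
                raise ValueError(f"offspring {off!r} has unknown dam {dam!r}")

    @property
    def offspring_ids(self) -> tuple[str, ...]:
        return tuple(o for o, _ in self.offspring)

    def family(self, dam_id: str) -> tuple[str, ...]:
        return tuple(o for o, d in self.offspring if d == dam_id)


@dataclass(frozen=True)
class GenotypeCallFilter:
    """Hard call-level filters applied before site selection.

    Defaults follow high-coverage pedigree practice: depth >= 15,
    site QUAL > 50, genotype quality >= 40, allelic balance (minor-read
    fraction) > 0.30 for heterozygote and < 0.07 for homozygote calls,
    biallelic SNPs only, with repeat regions excluded via BED intervals.
    """

    min_depth: int = 15
    min_qual: float = 50.0
    min_gq: int = 40
    het_ab_min: float = 0.30
    hom_ab_max: float = 0.07
    biallelic_snps_only: bool = True
    exclude_regions: dict[str, IntervalTree] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.hom_ab_max < self.het_ab_min <= 0.5):
            raise ValueError("require 0 <= hom_ab_max < het_ab_min <= 0.5")

    def excluded(self, chrom: str, pos0: int) -> bool:
        if self.exclude_regions is None:
            return False
        tree = self.exclude_regions.get(chrom)
        return bool(tree is not None and tree.overlaps(pos0))


@dataclass
class InheritanceMatrix:
    """Transmitted-allele matrix for one focal parent on one chromosome.

    ``M[i, j]`` is the allele (0 = reference, 1 = alternative) that the
    focal parent passed to offspring ``offspring_ids[j]`` at the marker
    with (0-based) position ``positions[i]``.
    """

    parent_role: str  # "paternal" or "maternal"
    parent_id: str
    chrom: str
    offspring_ids: tuple[str, ...]
    positions: np.ndarray  # (m,) int64, strictly increasing
    M: np.ndarray  # (m, n) uint8
    n_mendel_dropped: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.M = np.asarray(self.M, dtype=np.uint8)
        if self.M.shape != (len(self.positions), len(self.offspring_ids)):
            raise ValueError("matrix shape does not match positions/offspring")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("marker positions must be strictly increasing")


@dataclass(frozen=True)
class CrossoverEvent:
    """One inferred recombination, localised between two adjacent markers."""

    meiosis_id: tuple[str, str]  # (offspring_id, parental role)
    chrom: str
    left: int
    right: int
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.left >= self.right:
            raise ValueError("event interval must have left < right")


@dataclass(frozen=True)
class CrossoverClusterFlag:
    """>= cluster_min meioses recombining at the same locus."""

    chrom: str
    start: int
    end: int
    n_events: int
    meioses: tuple[tuple[str, str], ...]


# ---------------------------------------------------------------------------
# input plumbing
# ---------------------------------------------------------------------------

def read_pedigree_tsv(path) -> PedigreeSpec:
    """Pedigree TSV with columns id, sire, dam, sex ("0" = founder)."""
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if line.strip():
                rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    sires = {r["sire"] for r in rows if r["sire"] != "0"}
    dams = sorted({r["dam"] for r in rows if r["dam"] != "0"})
    if len(sires) != 1 or len(dams) != 2:
        raise ValueError("expected exactly one sire and two dams in pedigree file")
    (sire,) = sires
    offspring = tuple((r["id"], r["dam"]) for r in rows if r["sire"] != "0")
    return PedigreeSpec(sire_id=sire, dam_ids=(dams[0], dams[1]), offspring=offspring)


def read_bed_intervals(path) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split("\t")[:3]
            trees.setdefault(chrom, IntervalTree()).addi(int(start), int(end))
    return trees


# ---------------------------------------------------------------------------
# informative-site selection
# ---------------------------------------------------------------------------

class MissingFieldError(ValueError):
    pass


def _minor_fraction(ad_ref: int, ad_alt: int) -> float:
    tot = ad_ref + ad_alt
    if tot == 0:
        return 0.0
    return min(ad_ref, ad_alt) / tot


def select_informative_sites(
    vcf_path,
    pedigree: PedigreeSpec,
    filt: GenotypeCallFilter | None = None,
    role: str = "paternal",
) -> dict[str, pd.DataFrame]:
    """Select sites informative about the focal parent's transmissions.

    paternal role: sire heterozygous, both dams homozygous; maternal
    role: sire homozygous, both dams heterozygous.  Every offspring must
    carry a passing genotype call; multi-allelic records, non-SNPs,
    low-quality calls and excluded regions are dropped.

    Returns one table per chromosome with 0-based positions and the
    allele-count genotype (0/1/2) of every pedigree sample.
    """
    from cyvcf2 import VCF

    if role not in ("paternal", "maternal"):
        raise ValueError(f"role must be paternal or maternal, got {role!r}")
    filt = filt or GenotypeCallFilter()
    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    needed = [pedigree.sire_id, *pedigree.dam_ids, *pedigree.offspring_ids]
    for sid in needed:
        if sid not in samples:
            raise KeyError(f"sample {sid!r} missing from VCF header")
    idx = np.array([samples.index(s) for s in needed])
    n_off = len(pedigree.offspring_ids)

    out_rows: dict[str, list[tuple]] = {}
    for v in vcf:
        if filt.biallelic_snps_only and (
            len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1
        ):
            continue
        if v.QUAL is None or v.QUAL <= filt.min_qual:
            continue
        pos0 = v.POS - 1
        if filt.excluded(v.CHROM, pos0):
            continue
        gts = v.gt_types[idx]  # 0 hom-ref, 1 het, 2 hom-alt, 3 missing
        if np.any(gts == 3):
            continue
        sire_gt, dam1_gt, dam2_gt = gts[0], gts[1], gts[2]
        if role == "paternal":
            if not (sire_gt == 1 and dam1_gt in (0, 2) and dam2_gt in (0, 2)):
                continue
        else:
            if not (sire_gt in (0, 2) and dam1_gt == 1 and dam2_gt == 1):
                continue
        def _fmt(tag):
            try:
                return v.format(tag)
            except KeyError:
                return None

        dp = _fmt("DP")
        gq = _fmt("GQ")
        ad = _fmt("AD")
        if ad is None:
            raise MissingFieldError(
                f"{vcf_path}: AD field absent at {v.CHROM}:{v.POS}; "
                "allelic balance cannot be computed"
            )
        if dp is None or gq is None:
            raise MissingFieldError(
                f"{vcf_path}: DP/GQ fields required at {v.CHROM}:{v.POS}"
            )
        dp = dp.reshape(-1)[idx]
        gq = gq.reshape(-1)[idx]
        ad = ad.reshape(len(samples), -1)[idx]
        ok = True
        for k in range(len(needed)):
            if dp[k] < filt.min_depth or gq[k] < filt.min_gq:
                ok = False
                break
            ab = _minor_fraction(int(ad[k, 0]), int(ad[k, 1]))
            if gts[k] == 1:
                if ab <= filt.het_ab_min:
                    ok = False
                    break
            else:
                if ab >= filt.hom_ab_max:
                    ok = False
                    break
        if not ok:
            continue
        out_rows.setdefault(v.CHROM, []).append((pos0, *(int(g) for g in gts)))

    cols = ["pos", pedigree.sire_id, *pedigree.dam_ids, *pedigree.offspring_ids]
    return {
        chrom: pd.DataFrame(rows, columns=cols).drop_duplicates("pos")
        for chrom, rows in out_rows.items()
    }


# ---------------------------------------------------------------------------
# inheritance matrices
# ---------------------------------------------------------------------------

def build_inheritance_matrices(
    markers: dict[str, pd.DataFrame],
    pedigree: PedigreeSpec,
    role: str = "paternal",
) -> list[InheritanceMatrix]:
    """Derive transmitted alleles by Mendelian subtraction.

    paternal: one matrix per chromosome over all offspring (transmitted
    allele = offspring allele count minus the dam's homozygous allele).
    maternal: one matrix per chromosome per dam family, since the two
    dams' phases are independent.  Sites where a transmission is
    Mendelian-impossible are dropped (and counted), not error-corrected.
    """
    matrices: list[InheritanceMatrix] = []
    for chrom in sorted(markers):
        df = markers[chrom].sort_values("pos")
        if role == "paternal":
            groups = [(pedigree.sire_id, pedigree.offspring_ids, None)]
        else:
            groups = [
                (dam, pedigree.family(dam), dam) for dam in pedigree.dam_ids
            ]
        for parent_id, off_ids, dam in groups:
            if not off_ids:
                continue
            pos = df["pos"].to_numpy()
            off_gt = np.column_stack([df[o].to_numpy() for o in off_ids])
            if role == "paternal":
                # subtract each offspring's own dam's homozygous allele
                dam_of = dict(pedigree.offspring)
                other = np.column_stack(
                    [(df[dam_of[o]].to_numpy() == 2).astype(int) for o in off_ids]
                )
            else:
                other = np.tile(
                    (df[pedigree.sire_id].to_numpy() == 2).astype(int)[:, None],
                    (1, len(off_ids)),
                )
            T = off_gt - other
            consistent = ((T == 0) | (T == 1)).all(axis=1)
            dropped = int((~consistent).sum())
            positions = pos[consistent]
            rows = T[consistent]
            if len(positions) == 0:
                continue
            matrices.append(
                InheritanceMatrix(
                    parent_role=role,
                    parent_id=parent_id,
                    chrom=chrom,
                    offspring_ids=tuple(off_ids),
                    positions=np.array(positions),
                    M=np.array(rows, dtype=np.uint8),
                    n_mendel_dropped=dropped,
                )
            )
    return matrices


# ---------------------------------------------------------------------------
# minimum-recombinant inference
# ---------------------------------------------------------------------------

def _resolve_phase(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row phase flips realising the minimum crossover count.

    Returns (flips, ambiguous): ``flips[i]`` is 1 if row i is
    complemented in the painted matrix; ``ambiguous[i]`` marks intervals
    (between rows i and i+1) where d == n - d and both phase choices tie.
    Ties are broken so that the switching offspring set in the interval
    contains the lowest offspring index (a deterministic, lexicographic
    choice); totals are unaffected because min(d, n - d) is symmetric.
    """
    m, n = M.shape
    d = (M[1:] != M[:-1]).sum(axis=1)
    ambiguous = d * 2 == n
    flips = np.zeros(m, dtype=np.uint8)
    for i in range(m - 1):
        if d[i] * 2 > n:
            rel = 1
        elif d[i] * 2 < n:
            rel = 0
        else:
            # tie: pick the relative flip whose switch set contains column 0
            base_diff = (M[i] ^ flips[i]) != (M[i + 1] ^ flips[i])
            rel = 0 if base_diff[0] else 1
        flips[i + 1] = flips[i] ^ rel
    return flips, ambiguous


def _events_from_painting(
    matrix: InheritanceMatrix, painted: np.ndarray, ambiguous: np.ndarray
) -> list[CrossoverEvent]:
    events = []
    switches = painted[1:] != painted[:-1]
    for i, j in zip(*np.nonzero(switches)):
        events.append(
            CrossoverEvent(
                meiosis_id=(matrix.offspring_ids[j], matrix.parent_role),
                chrom=matrix.chrom,
                left=int(matrix.positions[i]),
                right=int(matrix.positions[i + 1]),
                ambiguous=bool(ambiguous[i]),
            )
        )
    return events


def min_crossovers(matrix: InheritanceMatrix) -> tuple[int, list[CrossoverEvent]]:
    """Minimum crossovers consistent with the matrix under unknown phase.

    The total is the sum over adjacent marker pairs of min(d, n - d),
    with d the Hamming distance between the two rows; the per-interval
    events are assigned to the smaller-side offspring set (ties flagged
    ambiguous).  Requires at least 2 markers and 1 offspring.
    """
    M = matrix.M
    m, n = M.shape
    if n == 0:
        raise ValueError("no offspring")
    if m < 2:
        raise ValueError("need at least 2 markers to place a crossover")
    flips, ambiguous = _resolve_phase(M)
    painted = M ^ flips[:, None]
    events = _events_from_painting(matrix, painted, ambiguous)
    d = (M[1:] != M[:-1]).sum(axis=1)
    total = int(np.minimum(d, n - d).sum())
    assert total == len(events)
    return total, events


def smooth_gene_conversions(
    events: list[CrossoverEvent],
    matrix: InheritanceMatrix,
    min_support: int = 2,
) -> list[CrossoverEvent]:
    """Drop switch pairs supported by fewer than ``min_support`` markers.

    An isolated one- or few-marker state excursion in a single offspring
    (typically a genotyping error or a gene conversion) induces two
    adjacent switches; both are removed by flipping the short interior
    run to its flanking state.  Runs at chromosome ends are kept: a
    terminal switch has no partner and may be a genuine crossover.  The
    crossover total never increases.
    """
    flips, ambiguous = _resolve_phase(matrix.M)
    painted = (matrix.M ^ flips[:, None]).astype(np.uint8)
    m, n = painted.shape
    for j in range(n):
        col = painted[:, j]
        changed = True
        while changed:
            changed = False
            # run-length encode the column
            bounds = [0] + list(np.nonzero(col[1:] != col[:-1])[0] + 1) + [m]
            for r in range(1, len(bounds) - 2):
                lo, hi = bounds[r], bounds[r + 1]
                if hi - lo < min_support:
                    col[lo:hi] = col[lo - 1]
                    changed = True
                    break
    smoothed = _events_from_painting(matrix, painted, ambiguous)
    if len(smoothed) > len(events):  # pragma: no cover - guarded by construction
        warnings.warn("smoothing increased event count; returning original events")
        return events
    return smoothed


# ---------------------------------------------------------------------------
# clustering and candidate labelling
# ---------------------------------------------------------------------------

def detect_crossover_clusters(
    events: list[CrossoverEvent],
    cluster_min: int = 3,
    merge_window: int = 50_000,
) -> list[CrossoverClusterFlag]:
    """Group co-located events across meioses and flag pile-ups.

    Each event interval is padded by ``merge_window / 2`` on both sides;
    padded intervals that overlap are merged (single linkage) and any
    group containing >= ``cluster_min`` events becomes a flag.  The flag
    interval reported is the span of the unpadded member intervals.
    """
    flags: list[CrossoverClusterFlag] = []
    pad = merge_window // 2
    by_chrom: dict[str, list[CrossoverEvent]] = {}
    for ev in events:
        by_chrom.setdefault(ev.chrom, []).append(ev)
    for chrom in sorted(by_chrom):
        evs = sorted(by_chrom[chrom], key=lambda e: (e.left, e.right))
        group: list[CrossoverEvent] = []
        group_end = -1
        for ev in evs + [None]:
            if ev is not None and (not group or ev.left - pad <= group_end):
                group.append(ev)
                group_end = max(group_end, ev.right + pad)
                continue
            if len(group) >= cluster_min:
                flags.append(
                    CrossoverClusterFlag(
                        chrom=chrom,
                        start=min(e.left for e in group),
                        end=max(e.right for e in group),
                        n_events=len(group),
                        meioses=tuple(e.meiosis_id for e in group),
                    )
                )
            if ev is not None:
                group = [ev]
                group_end = ev.right + pad
    return flags


class CoordinateSystemError(ValueError):
    pass


def _interval_distance(start: int, end: int, pos: int) -> int:
    if start <= pos < end:
        return 0
    return start - pos if pos < start else pos - (end - 1)


def proximity_label(
    intervals_by_chrom: dict[str, list[tuple[int, int]]],
    candidate: BreakpointCandidate,
    window: int,
) -> str:
    """Which of the candidate's breakpoints has evidence within ``window``."""
    near = []
    for pos in (candidate.a_start_bp, candidate.a_end_bp):
        hit = any(
            _interval_distance(s, e, pos) <= window
            for s, e in intervals_by_chrom.get(candidate.a_chrom, [])
        )
        near.append(hit)
    if all(near):
        return "start+end"
    if near[0]:
        return "start"
    if near[1]:
        return "end"
    return "no"


def linkage_evidence(
    flags: list[CrossoverClusterFlag],
    candidates: list[BreakpointCandidate],
    window: int = 50_000,
) -> dict[str, str]:
    """Label each candidate by crossover-cluster proximity.

    Flags and candidates must share a coordinate system; if both sets
    are non-empty but their chromosome names are disjoint, that is
    treated as a coordinate-system mix-up and raised rather than
    silently labelling everything "no".
    """
    if flags and candidates:
        if not ({f.chrom for f in flags} & {c.a_chrom for c in candidates}):
            raise CoordinateSystemError(
                "cluster flags and candidates share no chromosome names; "
                "are they on the same assembly?"
            )
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for f in flags:
        by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
    return {c.id: proximity_label(by_chrom, c, window) for c in candidates}


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_events_bed(events: list[CrossoverEvent], path) -> None:
    with open(path, "w") as fh:
        for e in sorted(events, key=lambda e: (e.chrom, e.left, e.right)):
            name = f"{e.meiosis_id[0]}:{e.meiosis_id[1]}"
            fh.write(f"{e.chrom}\t{e.left}\t{e.right}\t{name}\n")


def write_flags_bed(flags: list[CrossoverClusterFlag], path) -> None:
    with open(path, "w") as fh:
        for f in flags:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\tn={f.n_events}\n")


def write_painting_tsv(matrix: InheritanceMatrix, path) -> None:
    """Phase-resolved inheritance painting: one row per offspring.

    Entries are the painted haplotype states (0/1) whose switches along
    a row are the inferred crossovers - the red/blue row encoding of a
    recombination painting, in numeric form.
    """
    flips, _ = _resolve_phase(matrix.M)
    painted = matrix.M ^ flips[:, None]
    with open(path, "w") as fh:
        fh.write("offspring\t" + "\t".join(str(p) for p in matrix.positions) + "\n")
        for j, off in enumerate(matrix.offspring_ids):
            fh.write(off + "\t" + "\t".join(str(x) for x in painted[:, j]) + "\n")
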