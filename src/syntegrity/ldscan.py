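"""Recombination-rate anomaly scanning for misassembly evidence.

A misjoin in an assembly juxtaposes sequence that is not adjacent in the
population's real genome.  Linkage disequilibrium decays across such a
junction as if recombination there were extreme, so the population-scaled
recombination rate rho (= 4Nr, estimated from unrelated individuals,
e.g. by LDhelmet) shows a localised spike at the misjoin.  This module
scans a rho track for segments with total rho > 500 and rho/bp > 0.2 and
attaches that evidence to breakpoint candidates within 50 kb.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crossovers import proximity_label
from .synteny import AlignmentBlock, BreakpointCandidate, LiftoverMap

__all__ = [
    "RhoTrack",
    "HotSegment",
    "read_rho_track",
    "write_rho_track",
    "find_hot_segments",
    "ld_evidence",
    "write_segments_bed",
]


@dataclass(frozen=True)
class RhoTrack:
    """Per-interval rho/bp over 0-based half-open, non-overlapping intervals."""

    df: pd.DataFrame  # columns: chrom, start, end, rho_per_bp
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        if not np.all(np.isfinite(df["rho_per_bp"])) or (df["rho_per_bp"] < 0).any():
            raise ValueError("rho_per_bp must be finite and non-negative")
        if (df["end"] <= df["start"]).any():
            raise ValueError("intervals must be non-empty")
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        for chrom, sub in df.groupby("chrom", sort=False):
            overlap = sub["start"].values[1:] < sub["end"].values[:-1]
            if overlap.any():
                i = int(np.nonzero(overlap)[0][0])
                a = sub.iloc[i]
                b = sub.iloc[i + 1]
                raise ValueError(
                    f"overlapping intervals on {chrom}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        object.__setattr__(self, "df", df)

    def merged(self) -> "RhoTrack":
        """Merge adjacent intervals that share the same rate."""
        rows = []
        for chrom, sub in self.df.groupby("chrom", sort=False):
            cur = None
            for row in sub.itertuples(index=False):
                if (
                    cur is not None
                    and row.start == cur[2]
                    and math.isclose(row.rho_per_bp, cur[3], rel_tol=1e-12)
                ):
                    cur = (cur[0], cur[1], row.end, cur[3])
                else:
                    if cur is not None:
                        rows.append(cur)
                    cur = (chrom, row.start, row.end, row.rho_per_bp)
            if cur is not None:
                rows.append(cur)
        return RhoTrack(
            pd.DataFrame(rows, columns=["chrom", "start", "end", "rho_per_bp"]),
            provenance=self.provenance,
        )


@dataclass(frozen=True)
class HotSegment:
    """A maximal above-threshold run that also clears the total-rho bar."""

    chrom: str
    start: int
    end: int
    total_rho: float
    mean_rho_per_bp: float


def read_rho_track(path, dialect: str = "bed4", chrom: str | None = None) -> RhoTrack:
    """Read a rho track.

    bed4
        chrom, start, end, rho_per_bp; 0-based half-open.
    ldhelmet_post
        LDhelmet post-processed text: left_snp, right_snp, mean rho/bp
        (extra percentile columns ignored).  The file carries no
        chromosome name, so ``chrom`` must be supplied; the 1-based SNP
        positions bound the interval, stored as [left_snp-1, right_snp-1).

    Intervals are sorted and adjacent equal-rate duplicates merged;
    overlapping intervals are rejected.
    """
    if dialect == "bed4":
        df = pd.read_csv(
            path, sep="\t", comment="#",
            names=["chrom", "start", "end", "rho_per_bp"],
            dtype={"chrom": str},
        )
    elif dialect == "ldhelmet_post":
        if chrom is None:
            raise ValueError("ldhelmet_post dialect requires a chromosome name")
        raw = pd.read_csv(path, sep=r"\s+", comment="#", header=None)
        df = pd.DataFrame(
            {
                "chrom": chrom,
                "start": raw[0].astype(int) - 1,
                "end": raw[1].astype(int) - 1,
                "rho_per_bp": raw[2].astype(float),
            }
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return RhoTrack(df, provenance=f"{dialect}:{path}").merged()


def write_rho_track(track: RhoTrack, path, dialect: str = "bed4") -> None:
    if dialect != "bed4":
        raise ValueError("only the bed4 dialect is written")
    track.df.to_csv(path, sep="\t", header=False, index=False)


def find_hot_segments(
    track: RhoTrack,
    rho_bp_min: float = 0.2,
    total_rho_min: float = 500.0,
    merge_gap: int = 0,
) -> list[HotSegment]:
    """Maximal runs with rho/bp strictly above ``rho_bp_min`` whose
    summed rho (rate x interval length) strictly exceeds ``total_rho_min``.

    Consecutive above-threshold intervals separated by <= ``merge_gap``
    bp of track gap are bridged (the gap contributes no rho).  Output is
    position-sorted.
    """
    segments: list[HotSegment] = []
    for chrom, sub in track.df.groupby("chrom", sort=True):
        run: list[tuple[int, int, float]] = []
        prev_end = None
        for row in sub.itertuples(index=False):
            hot = row.rho_per_bp > rho_bp_min
            contiguous = prev_end is not None and row.start - prev_end <= merge_gap
            if hot and run and contiguous:
                run.append((row.start, row.end, row.rho_per_bp))
            elif hot:
                if run:
                    segments.extend(_emit(chrom, run, total_rho_min))
                run = [(row.start, row.end, row.rho_per_bp)]
            else:
                if run:
                    segments.extend(_emit(chrom, run, total_rho_min))
                run = []
            prev_end = row.end
        if run:
            segments.extend(_emit(chrom, run, total_rho_min))
    segments.sort(key=lambda s: (s.chrom, s.start))
    return segments


def _emit(chrom: str, run: list[tuple[int, int, float]], total_min: float) -> list[HotSegment]:
    total = sum(r * (e - s) for s, e, r in run)
    covered = sum(e - s for s, e, _ in run)
    if total > total_min:
        return [
            HotSegment(
                chrom=chrom,
                start=run[0][0],
                end=run[-1][1],
                total_rho=total,
                mean_rho_per_bp=total / covered,
            )
        ]
    return []


def ld_evidence(
    segments: list[HotSegment],
    candidates: list[BreakpointCandidate],
    window: int = 50_000,
    chains_for_liftover: list[AlignmentBlock] | LiftoverMap | None = None,
) -> dict[str, str]:
    """Label candidates by hot-segment proximity (within ``window``).

    When the rho track lives on a different assembly than the
    candidates, supply alignment blocks (candidate assembly as A, track
    assembly as B): each breakpoint is lifted before the proximity test.
    A breakpoint that fails to lift, or a candidate whose two lifted
    breakpoints land on different track chromosomes (so cross-assembly
    synteny cannot be verified across the event), is labelled
    "unknown" - never silently dropped.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append((s.start, s.end))
    lom: LiftoverMap | None = None
    if chains_for_liftover is not None:
        lom = (
            chains_for_liftover
            if isinstance(chains_for_liftover, LiftoverMap)
            else LiftoverMap(chains_for_liftover)
        )
    labels: dict[str, str] = {}
    for c in candidates:
        if lom is not None:
            lifted = [lom.lift(c.a_chrom, c.a_start_bp), lom.lift(c.a_chrom, c.a_end_bp)]
            if any(x is None for x in lifted) or lifted[0][0] != lifted[1][0]:
                labels[c.id] = "unknown"
                continue
            chrom = lifted[0][0]
            lo, hi = sorted((lifted[0][1], lifted[1][1]))
            probe = BreakpointCandidate(
                kind=c.kind, a_chrom=chrom, a_start_bp=lo, a_end_bp=max(hi, lo + 1),
                b_chrom=c.b_chrom, b_start_bp=c.b_start_bp, b_end_bp=c.b_end_bp,
            )
        else:
            probe = c
        labels[c.id] = proximity_label(by_chrom, probe, window)
    return labels


def write_segments_bed(segments: list[HotSegment], path) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t"
                f"total={s.total_rho:.1f};mean={s.mean_rho_per_bp:.4f}\n"
            )
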