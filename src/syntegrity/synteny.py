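"""Synteny-break detection between two genome assemblies.

Starting from whole-genome alignment blocks (nucmer ``show-coords``-style
tables or PAF), this module chains co-linear blocks into syntenic runs,
flags large (>100 kb by default) discordances as inversion or
translocation candidates, lifts coordinates across the two assemblies
through the aligned blocks, and exports dot-plot data.

Coordinates are 0-based half-open throughout the in-memory model; the
1-based inclusive convention of nucmer coords tables is converted at the
file boundary.  Assembly "A" is the assembly whose coordinates index the
candidates (conventionally the assembly being audited); assembly "B" is
the other one.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "AlignmentBlock",
    "SyntenyChain",
    "BreakpointCandidate",
    "read_alignment_blocks",
    "write_alignment_blocks",
    "swap_assemblies",
    "chain_blocks",
    "detect_breaks",
    "LiftoverMap",
    "lift_coordinate",
    "export_dotplot",
    "write_candidates_tsv",
    "read_candidates_tsv",
    "write_breakpoints_bed",
]


@dataclass(frozen=True)
class AlignmentBlock:
    """One aligned interval pair between assemblies A and B.

    Both intervals are stored in forward (ascending) coordinates; a
    reverse-strand alignment is recorded with ``orientation == "-"``.
    """

    a_chrom: str
    a_start: int
    a_end: int
    b_chrom: str
    b_start: int
    b_end: int
    orientation: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise ValueError(f"orientation must be + or -, got {self.orientation!r}")
        if not (self.a_end > self.a_start and self.b_end > self.b_start):
            raise ValueError(
                f"inverted or empty interval in block {self.a_chrom}:"
                f"{self.a_start}-{self.a_end} / {self.b_chrom}:{self.b_start}-{self.b_end}"
            )

    @property
    def length(self) -> int:
        return self.a_end - self.a_start

    def swapped(self) -> "AlignmentBlock":
        """The same alignment viewed from assembly B."""
        return AlignmentBlock(
            self.b_chrom, self.b_start, self.b_end,
            self.a_chrom, self.a_start, self.a_end, self.orientation,
        )


@dataclass(frozen=True)
class SyntenyChain:
    """A maximal run of co-linear, same-orientation blocks."""

    blocks: tuple[AlignmentBlock, ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("empty chain")
        if len({b.orientation for b in self.blocks}) != 1:
            raise ValueError("mixed orientations within a chain")

    @property
    def a_chrom(self) -> str:
        return self.blocks[0].a_chrom

    @property
    def b_chrom(self) -> str:
        return self.blocks[0].b_chrom

    @property
    def orientation(self) -> str:
        return self.blocks[0].orientation

    @property
    def a_start(self) -> int:
        return self.blocks[0].a_start

    @property
    def a_end(self) -> int:
        return self.blocks[-1].a_end

    @property
    def b_start(self) -> int:
        return min(b.b_start for b in self.blocks)

    @property
    def b_end(self) -> int:
        return max(b.b_end for b in self.blocks)

    @property
    def a_span(self) -> tuple[int, int]:
        return (self.a_start, self.a_end)

    @property
    def b_span(self) -> tuple[int, int]:
        return (self.b_start, self.b_end)


@dataclass(frozen=True)
class BreakpointCandidate:
    """A large inversion (Inv) or translocation (Trans) discordance.

    ``a_start_bp`` and ``a_end_bp`` are the two breakpoints in assembly
    A; the candidate's size is the distance between them.
    """

    kind: str  # "Inv" or "Trans"
    a_chrom: str
    a_start_bp: int
    a_end_bp: int
    b_chrom: str
    b_start_bp: int
    b_end_bp: int

    def __post_init__(self) -> None:
        if self.kind not in ("Inv", "Trans"):
            raise ValueError(f"kind must be Inv or Trans, got {self.kind!r}")
        if self.a_end_bp <= self.a_start_bp:
            raise ValueError("a_end_bp must exceed a_start_bp")

    @property
    def size(self) -> int:
        return self.a_end_bp - self.a_start_bp

    @property
    def id(self) -> str:
        return f"{self.a_chrom}:{self.a_start_bp}-{self.a_end_bp}:{self.kind}"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _check_length_ratio(block: AlignmentBlock, tol: float) -> bool:
    la = block.a_end - block.a_start
    lb = block.b_end - block.b_start
    return abs(la - lb) <= tol * max(la, lb)


def read_alignment_blocks(
    path,
    dialect: str = "coords",
    length_ratio_tol: float = 0.20,
    reject_discordant_lengths: bool = True,
) -> list[AlignmentBlock]:
    """Read alignment blocks from a coords table or a PAF file.

    coords dialect
        Tab-separated, headerless, in the spirit of
        ``show-coords -THrd``: columns S1, E1, S2, E2, LEN1, LEN2, %IDY,
        REF_NAME, QRY_NAME.  Coordinates are 1-based inclusive and a
        reverse-strand hit has S2 > E2.  REF is assembly A, QRY is B.

    paf dialect
        Standard minimap2 PAF (first 12 columns used); the query is
        assembly A and the target assembly B.  PAF is already 0-based
        half-open with target intervals in forward coordinates.

    Blocks whose A- and B-lengths differ by more than ``length_ratio_tol``
    (indel tolerance) are rejected (``reject_discordant_lengths=True``)
    or kept, per configuration.  Malformed lines raise with the line
    number.
    """
    blocks: list[AlignmentBlock] = []
    if dialect not in ("coords", "paf"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "coords":
                    s1, e1, s2, e2 = (int(x) for x in fields[:4])
                    a_chrom, b_chrom = fields[7], fields[8]
                    if s2 <= e2:
                        orient = "+"
                        b_lo, b_hi = s2 - 1, e2
                    else:
                        orient = "-"
                        b_lo, b_hi = e2 - 1, s2
                    block = AlignmentBlock(a_chrom, s1 - 1, e1, b_chrom, b_lo, b_hi, orient)
                else:
                    a_chrom = fields[0]
                    a_start, a_end = int(fields[2]), int(fields[3])
                    orient = fields[4]
                    b_chrom = fields[5]
                    b_start, b_end = int(fields[7]), int(fields[8])
                    block = AlignmentBlock(a_chrom, a_start, a_end, b_chrom, b_start, b_end, orient)
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            if reject_discordant_lengths and not _check_length_ratio(block, length_ratio_tol):
                continue
            blocks.append(block)
    return blocks


def write_alignment_blocks(blocks: list[AlignmentBlock], path, dialect: str = "coords") -> None:
    """Write blocks in the same layout `read_alignment_blocks` accepts."""
    with open(path, "w") as fh:
        for b in blocks:
            la, lb = b.a_end - b.a_start, b.b_end - b.b_start
            if dialect == "coords":
                if b.orientation == "+":
                    s2, e2 = b.b_start + 1, b.b_end
                else:
                    s2, e2 = b.b_end, b.b_start + 1
                fh.write(
                    f"{b.a_start + 1}\t{b.a_end}\t{s2}\t{e2}\t{la}\t{lb}\t100.00"
                    f"\t{b.a_chrom}\t{b.b_chrom}\n"
                )
            elif dialect == "paf":
                fh.write(
                    f"{b.a_chrom}\t0\t{b.a_start}\t{b.a_end}\t{b.orientation}"
                    f"\t{b.b_chrom}\t0\t{b.b_start}\t{b.b_end}\t{min(la, lb)}\t{max(la, lb)}\t60\n"
                )
            else:
                raise ValueError(f"unknown dialect {dialect!r}")


def swap_assemblies(blocks: list[AlignmentBlock]) -> list[AlignmentBlock]:
    """View the alignment from assembly B's perspective."""
    return [b.swapped() for b in blocks]


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

def _extends_chain(prev: AlignmentBlock, nxt: AlignmentBlock, max_gap: int) -> bool:
    """Whether `nxt` continues the chain ending in `prev` co-linearly."""
    if nxt.a_chrom != prev.a_chrom or nxt.b_chrom != prev.b_chrom:
        return False
    if nxt.orientation != prev.orientation:
        return False
    if nxt.a_start - prev.a_end > max_gap:
        return False
    if prev.orientation == "+":
        # b offsets must keep increasing
        if nxt.b_start < prev.b_end - _OVERLAP_SLOP:
            return False
        return nxt.b_start - prev.b_end <= max_gap
    # "-": b offsets must keep decreasing as a increases
    if nxt.b_end > prev.b_start + _OVERLAP_SLOP:
        return False
    return prev.b_start - nxt.b_end <= max_gap


#: nucmer chains routinely overlap by repeat margins; permit this much
#: backtracking in b before declaring two blocks non-co-linear.
_OVERLAP_SLOP = 0


def chain_blocks(
    blocks: list[AlignmentBlock],
    min_block: int = 10_000,
    max_gap: int = 200_000,
) -> list[SyntenyChain]:
    """Greedily chain co-linear, same-orientation blocks.

    Blocks shorter than ``min_block`` (on assembly A) are discarded first
    to suppress repeat-driven noise.  The remainder are sorted by
    (a_chrom, a_start) and swept left to right: a new chain starts
    whenever the next block changes a- or b-chromosome or orientation,
    breaks b-monotonicity for the chain's orientation, or leaves a gap
    larger than ``max_gap`` on either assembly.  Every retained block
    lands in exactly one chain.
    """
    kept = sorted(
        (b for b in blocks if b.length >= min_block),
        key=lambda b: (b.a_chrom, b.a_start, b.a_end),
    )
    chains: list[SyntenyChain] = []
    run: list[AlignmentBlock] = []
    for block in kept:
        if run and _extends_chain(run[-1], block, max_gap):
            run.append(block)
        else:
            if run:
                chains.append(SyntenyChain(tuple(run)))
            run = [block]
    if run:
        chains.append(SyntenyChain(tuple(run)))
    return chains


# ---------------------------------------------------------------------------
# break detection
# ---------------------------------------------------------------------------

def detect_breaks(
    chains: list[SyntenyChain],
    min_size: int = 100_000,
    max_gap: int = 200_000,
) -> list[BreakpointCandidate]:
    """Flag chains discordant with the chromosome's majority layout.

    Within each A-chromosome (chains sorted by a_start), the majority
    layout is a length-weighted backbone: the B-chromosome carrying most
    aligned length, its dominant orientation, and - among that
    chromosome's chains - the heaviest b-monotone subsequence
    (a weighted longest-increasing-subsequence, with ``max_gap`` of
    slack so small repeat-driven jitter is not called displacement).
    Then:

    * a chain mapping to a foreign B-chromosome is a translocation;
    * a chain off the monotone backbone is a translocation (its B
      interval is displaced out of order);
    * a chain on the backbone but in the minority orientation is an
      inversion.

    Only the minority side of a disagreement is reported, so detection
    is symmetric in the two assemblies.  Breakpoints are the midpoints
    between a flagged chain and its neighbours; candidates not larger
    than ``min_size`` are suppressed and output is ordered by size
    descending.
    """
    by_achrom: dict[str, list[SyntenyChain]] = {}
    for ch in chains:
        by_achrom.setdefault(ch.a_chrom, []).append(ch)
    candidates: list[BreakpointCandidate] = []
    for a_chrom, group in by_achrom.items():
        group = sorted(group, key=lambda c: c.a_start)
        if len(group) < 2:
            continue
        chrom_weight: dict[str, int] = {}
        orient_weight: dict[tuple[str, str], int] = {}
        for ch in group:
            span = ch.a_end - ch.a_start
            chrom_weight[ch.b_chrom] = chrom_weight.get(ch.b_chrom, 0) + span
            key = (ch.b_chrom, ch.orientation)
            orient_weight[key] = orient_weight.get(key, 0) + span
        dominant_b = max(chrom_weight, key=chrom_weight.get)

        def _dominant_orientation(b_chrom: str) -> str:
            fwd = orient_weight.get((b_chrom, "+"), 0)
            rev = orient_weight.get((b_chrom, "-"), 0)
            return "+" if fwd >= rev else "-"

        backbone: set[int] = set()
        for b_chrom in chrom_weight:
            idx = [i for i, ch in enumerate(group) if ch.b_chrom == b_chrom]
            backbone |= _weighted_monotone_backbone(
                group, idx, _dominant_orientation(b_chrom), max_gap
            )

        for i, chain in enumerate(group):
            if chain.b_chrom != dominant_b:
                kind = "Trans"
            elif i not in backbone:
                kind = "Trans"
            elif chain.orientation != _dominant_orientation(chain.b_chrom):
                kind = "Inv"
            else:
                continue
            left = group[i - 1] if i > 0 else None
            right = group[i + 1] if i + 1 < len(group) else None
            a_lo = (left.a_end + chain.a_start) // 2 if left is not None else chain.a_start
            a_hi = (chain.a_end + right.a_start) // 2 if right is not None else chain.a_end
            if a_hi - a_lo <= min_size:
                continue
            candidates.append(
                BreakpointCandidate(
                    kind=kind,
                    a_chrom=a_chrom,
                    a_start_bp=a_lo,
                    a_end_bp=a_hi,
                    b_chrom=chain.b_chrom,
                    b_start_bp=chain.b_start,
                    b_end_bp=chain.b_end,
                )
            )
    candidates.sort(key=lambda c: (-c.size, c.a_chrom, c.a_start_bp))
    return candidates


def _weighted_monotone_backbone(
    group: list[SyntenyChain], idx: list[int], direction: str, slack: int
) -> set[int]:
    """Indices of the heaviest b-monotone chain subsequence.

    Chains are taken in a-order; chain j may follow chain i when j's
    b midpoint advances in ``direction`` relative to i's, allowing
    ``slack`` bp of backtracking.  Weight is a-length, so a long
    in-place chain is never sacrificed to keep a short displaced one.
    """
    if not idx:
        return set()
    sign = 1 if direction == "+" else -1
    mids = [sign * (group[i].b_start + group[i].b_end) // 2 for i in idx]
    weights = [group[i].a_end - group[i].a_start for i in idx]
    k = len(idx)
    best = list(weights)
    prev = [-1] * k
    for j in range(k):
        for i in range(j):
            if mids[j] >= mids[i] - slack and best[i] + weights[j] > best[j]:
                best[j] = best[i] + weights[j]
                prev[j] = i
    end = max(range(k), key=lambda j: best[j])
    keep: set[int] = set()
    while end != -1:
        keep.add(idx[end])
        end = prev[end]
    return keep


# ---------------------------------------------------------------------------
# liftover
# ---------------------------------------------------------------------------

class LiftoverMap:
    """Point liftover A -> B through aligned blocks.

    Positions in unaligned gaps return None ("unmapped") rather than a
    nearest-block guess.
    """

    def __init__(self, blocks: list[AlignmentBlock]):
        self._by_chrom: dict[str, tuple[list[int], list[AlignmentBlock]]] = {}
        for chrom in {b.a_chrom for b in blocks}:
            sub = sorted(
                (b for b in blocks if b.a_chrom == chrom), key=lambda b: b.a_start
            )
            self._by_chrom[chrom] = ([b.a_start for b in sub], sub)
        self._blocks = list(blocks)

    def lift(self, chrom: str, pos: int) -> tuple[str, int] | None:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, sub = entry
        i = bisect.bisect_right(starts, pos) - 1
        if i < 0:
            return None
        b = sub[i]
        if not (b.a_start <= pos < b.a_end):
            return None
        if b.orientation == "+":
            return b.b_chrom, b.b_start + (pos - b.a_start)
        return b.b_chrom, b.b_end - 1 - (pos - b.a_start)

    def inverse(self) -> "LiftoverMap":
        return LiftoverMap(swap_assemblies(self._blocks))


def lift_coordinate(
    blocks: list[AlignmentBlock] | LiftoverMap, chrom: str, pos: int
) -> tuple[str, int] | None:
    """Lift one position from assembly A to assembly B (None if unmapped)."""
    lom = blocks if isinstance(blocks, LiftoverMap) else LiftoverMap(blocks)
    return lom.lift(chrom, pos)


# ---------------------------------------------------------------------------
# dot plots and tabular output
# ---------------------------------------------------------------------------

def export_dotplot(blocks, tsv_path=None, png_path=None) -> pd.DataFrame:
    """Dot-plot data: one (a_mid, b_mid, orientation) point per block.

    Accepts blocks or chains (chains are expanded to their blocks).
    Midpoints are reported in Mb.  When ``png_path`` is given, a scatter
    is rendered with the conventional colouring: purple for consistent
    (+) orientation, blue for inconsistent (-).
    """
    expanded: list[AlignmentBlock] = []
    for item in blocks:
        if isinstance(item, SyntenyChain):
            expanded.extend(item.blocks)
        else:
            expanded.append(item)
    df = pd.DataFrame(
        {
            "a_chrom": [b.a_chrom for b in expanded],
            "b_chrom": [b.b_chrom for b in expanded],
            "a_mid_mb": [(b.a_start + b.a_end) / 2e6 for b in expanded],
            "b_mid_mb": [(b.b_start + b.b_end) / 2e6 for b in expanded],
            "orientation": [b.orientation for b in expanded],
        }
    )
    if tsv_path is not None:
        df.to_csv(tsv_path, sep="\t", index=False)
    if png_path is not None and len(df):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 6))
        for orient, colour in (("+", "purple"), ("-", "tab:blue")):
            sel = df[df["orientation"] == orient]
            ax.scatter(sel["a_mid_mb"], sel["b_mid_mb"], s=4, c=colour, label=orient)
        ax.set_xlabel("assembly A (Mb)")
        ax.set_ylabel("assembly B (Mb)")
        ax.legend(title="orientation")
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
    return df


def write_candidates_tsv(candidates: list[BreakpointCandidate], path) -> None:
    """Candidate table with Mb coordinates rounded to 2 decimals."""
    with open(path, "w") as fh:
        fh.write(
            "candidate_id\ta_chrom\ta_start_mb\ta_end_mb\tb_chrom\tb_start_mb\tb_end_mb\ttype\tsize_bp\n"
        )
        for c in candidates:
            fh.write(
                f"{c.id}\t{c.a_chrom}\t{c.a_start_bp / 1e6:.2f}\t{c.a_end_bp / 1e6:.2f}"
                f"\t{c.b_chrom}\t{c.b_start_bp / 1e6:.2f}\t{c.b_end_bp / 1e6:.2f}"
                f"\t{c.kind}\t{c.size}\n"
            )


def read_candidates_tsv(path) -> list[BreakpointCandidate]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        chrom, span, kind = row["candidate_id"].split(":")
        lo, hi = (int(x) for x in span.split("-"))
        out.append(
            BreakpointCandidate(
                kind=kind,
                a_chrom=row["a_chrom"],
                a_start_bp=lo,
                a_end_bp=hi,
                b_chrom=row["b_chrom"],
                b_start_bp=int(round(row["b_start_mb"] * 1e6)),
                b_end_bp=int(round(row["b_end_mb"] * 1e6)),
            )
        )
    return out


def write_breakpoints_bed(candidates: list[BreakpointCandidate], path) -> None:
    """One BED line per breakpoint (two per candidate), on assembly A."""
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f"{c.a_chrom}\t{c.a_start_bp}\t{c.a_start_bp + 1}\t{c.id}:start\n")
            fh.write(f"{c.a_chrom}\t{c.a_end_bp}\t{c.a_end_bp + 1}\t{c.id}:end\n")
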