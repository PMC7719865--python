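"""Scaffold and contig statistics for genome assemblies.

An assembly is a set of scaffolds: sequences over {A, C, G, T, N} in which
runs of N denote gaps of estimated length between sequenced contigs.
This module computes the standard per-assembly summary (total length,
sequence count, N50, gap length) at both the scaffold and the contig
level, where contigs are obtained by splitting each scaffold at every
run of one or more N characters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import SeqIO

__all__ = [
    "SequenceSet",
    "AssemblyStats",
    "read_fasta",
    "split_into_contigs",
    "compute_stats",
    "write_stats_tsv",
    "STATS_COLUMNS",
]

_VALID = frozenset("ACGTN")
_N_RUN = re.compile(r"N+")

#: Column names used in the TSV report, in output order.
STATS_COLUMNS = (
    "Total length of scaffolds",
    "No. of scaffolds",
    "Scaffold N50",
    "Total gap length",
    "Total length of contigs",
    "No. of contigs",
    "Contig N50",
)


@dataclass(frozen=True)
class SequenceSet:
    """A named collection of DNA sequences.

    Sequences are normalised to upper case at construction.  Only the
    characters A, C, G, T and N are accepted; anything else (including
    other IUPAC ambiguity codes) is rejected with the offending record
    and position named, because gap accounting is only defined over the
    five-letter alphabet.
    """

    records: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        normalised = []
        for name, seq in self.records:
            if name in seen:
                raise ValueError(f"duplicate sequence identifier {name!r}")
            seen.add(name)
            if len(seq) == 0:
                raise ValueError(f"zero-length sequence {name!r}")
            seq = seq.upper()
            bad = set(seq) - _VALID
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise ValueError(
                    f"non-ACGTN character {seq[pos]!r} in {name!r} at position {pos}"
                )
            normalised.append((name, seq))
        object.__setattr__(self, "records", normalised)

    def __len__(self) -> int:
        return len(self.records)

    def lengths(self) -> list[int]:
        return [len(seq) for _, seq in self.records]


@dataclass(frozen=True)
class AssemblyStats:
    total_scaffold_length: int
    n_scaffolds: int
    scaffold_n50: int
    total_gap_length: int
    total_contig_length: int
    n_contigs: int
    contig_n50: int

    def as_row(self) -> dict[str, int]:
        return dict(
            zip(
                STATS_COLUMNS,
                (
                    self.total_scaffold_length,
                    self.n_scaffolds,
                    self.scaffold_n50,
                    self.total_gap_length,
                    self.total_contig_length,
                    self.n_contigs,
                    self.contig_n50,
                ),
            )
        )


def read_fasta(path) -> SequenceSet:
    """Read a (possibly line-wrapped, multi-record) FASTA file."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return SequenceSet(records)


def split_into_contigs(scaffolds: SequenceSet) -> SequenceSet:
    """Split every scaffold at each run of >=1 N.

    Empty fragments arising from leading, trailing or adjacent N-runs are
    dropped, so the result contains no N at all.  Contigs are named
    ``<scaffold>_ctg<k>`` with k numbered 1.. in scaffold order, which
    keeps identifiers unique.
    """
    out: list[tuple[str, str]] = []
    for name, seq in scaffolds.records:
        k = 0
        for frag in _N_RUN.split(seq):
            if frag:
                k += 1
                out.append((f"{name}_ctg{k}", frag))
    return SequenceSet(out)


def n50(lengths: list[int]) -> int:
    """N50: the largest L such that sequences of length >= L sum to at
    least half the total length.

    Equivalently (the convention used by assembler reports): sort the
    lengths in descending order and return the first length at which the
    running sum reaches half the total.
    """
    if not lengths:
        return 0
    total = sum(lengths)
    half = total / 2
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


def compute_stats(scaffolds: SequenceSet) -> AssemblyStats:
    """Compute the seven-number assembly summary.

    The gap length is simply the number of N characters, so
    ``total_scaffold_length == total_contig_length + total_gap_length``
    holds by construction.
    """
    if len(scaffolds) == 0:
        raise ValueError("empty sequence set")
    scaffold_lengths = scaffolds.lengths()
    contigs = split_into_contigs(scaffolds)
    contig_lengths = contigs.lengths()
    total_scaffold = sum(scaffold_lengths)
    total_contig = sum(contig_lengths)
    return AssemblyStats(
        total_scaffold_length=total_scaffold,
        n_scaffolds=len(scaffolds),
        scaffold_n50=n50(scaffold_lengths),
        total_gap_length=total_scaffold - total_contig,
        total_contig_length=total_contig,
        n_contigs=len(contigs),
        contig_n50=n50(contig_lengths) if contig_lengths else 0,
    )


def write_stats_tsv(stats: AssemblyStats, path) -> None:
    row = stats.as_row()
    with open(path, "w") as fh:
        fh.write("\t".join(STATS_COLUMNS) + "\n")
        fh.write("\t".join(str(row[c]) for c in STATS_COLUMNS) + "\n")
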