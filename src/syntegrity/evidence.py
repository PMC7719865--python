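"""Evidence integration: merge per-candidate support into a report.

Each large synteny-break candidate is annotated with three independent
evidence sources: pedigree linkage (crossover-cluster proximity),
optical-map support (externally supplied flags; map alignment itself is
out of scope here), and LD-based recombination-rate anomalies.  A
candidate is *corroborated* when at least one source is positive;
"no" and "unknown" are inconclusive and never corroborate, because the
absence of a signal in any one source does not support the audited
assembly being correct.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .synteny import BreakpointCandidate

__all__ = [
    "EvidenceRecord",
    "SupportSummary",
    "assemble_evidence",
    "summarize_support",
    "render_report",
    "parse_report",
    "read_bng_flags",
    "POSITIVE_LABELS",
]

_DIRECTIONAL = frozenset({"start", "end", "start+end", "no", "unknown"})
_BNG = frozenset({"yes", "no", "unknown"})

#: Labels that count as positive support from any source.
POSITIVE_LABELS = frozenset({"yes", "start", "end", "start+end"})

_COLUMNS = [
    "a_chrom", "a_start_mb", "a_end_mb", "b_chrom", "b_start_mb", "b_end_mb",
    "type", "linkage_support", "bng_support", "ld_support",
]


@dataclass(frozen=True)
class EvidenceRecord:
    candidate: BreakpointCandidate
    linkage_support: str = "unknown"
    bng_support: str = "unknown"
    ld_support: str = "unknown"

    def __post_init__(self) -> None:
        if self.linkage_support not in _DIRECTIONAL:
            raise ValueError(f"bad linkage label {self.linkage_support!r}")
        if self.ld_support not in _DIRECTIONAL:
            raise ValueError(f"bad LD label {self.ld_support!r}")
        if self.bng_support not in _BNG:
            raise ValueError(f"bad optical-map label {self.bng_support!r}")

    @property
    def corroborated(self) -> bool:
        return any(
            lab in POSITIVE_LABELS
            for lab in (self.linkage_support, self.bng_support, self.ld_support)
        )


@dataclass(frozen=True)
class SupportSummary:
    n_candidates: int
    n_corroborated: int
    per_source: dict[str, int]  # positive-count per evidence source

    def __post_init__(self) -> None:
        if self.n_corroborated > self.n_candidates:
            raise ValueError("corroborated count exceeds candidate count")


def read_bng_flags(path) -> dict[str, str]:
    """Optical-map support flags: TSV of candidate_id, flag {yes,no,unknown}."""
    df = pd.read_csv(path, sep="\t", names=["candidate_id", "flag"], comment="#")
    return dict(zip(df["candidate_id"], df["flag"].str.lower()))


def assemble_evidence(
    candidates: list[BreakpointCandidate],
    linkage_labels: dict[str, str] | None = None,
    ld_labels: dict[str, str] | None = None,
    bng_flags: dict[str, str] | None = None,
) -> list[EvidenceRecord]:
    """One record per candidate, sorted by size descending.

    Label dictionaries are keyed by candidate id; a missing source (or a
    missing key) yields "unknown".  A label for an id that matches no
    candidate is an error - it usually means labels were computed on a
    different candidate set.
    """
    known = {c.id for c in candidates}
    for name, labels in (
        ("linkage", linkage_labels), ("ld", ld_labels), ("bng", bng_flags)
    ):
        if labels:
            stray = set(labels) - known
            if stray:
                raise KeyError(
                    f"{name} labels refer to unknown candidate ids: {sorted(stray)[:3]}"
                )
    records = [
        EvidenceRecord(
            candidate=c,
            linkage_support=(linkage_labels or {}).get(c.id, "unknown"),
            ld_support=(ld_labels or {}).get(c.id, "unknown"),
            bng_support=(bng_flags or {}).get(c.id, "unknown"),
        )
        for c in candidates
    ]
    records.sort(key=lambda r: (-r.candidate.size, r.candidate.a_chrom))
    return records


def summarize_support(records: list[EvidenceRecord]) -> SupportSummary:
    """Count candidates with >=1 positive evidence source."""
    per_source = {
        "linkage": sum(r.linkage_support in POSITIVE_LABELS for r in records),
        "bng": sum(r.bng_support in POSITIVE_LABELS for r in records),
        "ld": sum(r.ld_support in POSITIVE_LABELS for r in records),
    }
    return SupportSummary(
        n_candidates=len(records),
        n_corroborated=sum(r.corroborated for r in records),
        per_source=per_source,
    )


def _record_row(r: EvidenceRecord) -> list[str]:
    c = r.candidate
    return [
        c.a_chrom, f"{c.a_start_bp / 1e6:.2f}", f"{c.a_end_bp / 1e6:.2f}",
        c.b_chrom, f"{c.b_start_bp / 1e6:.2f}", f"{c.b_end_bp / 1e6:.2f}",
        c.kind, r.linkage_support, r.bng_support, r.ld_support,
    ]


_CAVEAT = (
    "# The following regions lack definitive evidence; the correct "
    "orientation/placement cannot be determined and they should be "
    "considered provisional."
)


def render_report(
    records: list[EvidenceRecord],
    summary: SupportSummary,
    path,
    fmt: str = "tsv",
) -> None:
    """Write the evidence table (coordinates in Mb, 2 decimals).

    Corroborated candidates are listed first; provisional ones (no
    positive source) follow in a second table introduced by a caveat
    line.  Output is deterministic for fixed input.
    """
    corro = [r for r in records if r.corroborated]
    provisional = [r for r in records if not r.corroborated]
    with open(path, "w") as fh:
        if fmt == "tsv":
            fh.write("\t".join(_COLUMNS) + "\n")
            for r in corro:
                fh.write("\t".join(_record_row(r)) + "\n")
            if provisional:
                fh.write(_CAVEAT + "\n")
                for r in provisional:
                    fh.write("\t".join(_record_row(r)) + "\n")
            fh.write(
                f"# corroborated {summary.n_corroborated} of "
                f"{summary.n_candidates} candidates\n"
            )
        elif fmt == "markdown":
            fh.write("| " + " | ".join(_COLUMNS) + " |\n")
            fh.write("|" + "---|" * len(_COLUMNS) + "\n")
            for r in corro:
                fh.write("| " + " | ".join(_record_row(r)) + " |\n")
            if provisional:
                fh.write("\n" + _CAVEAT.lstrip("# ") + "\n\n")
                fh.write("| " + " | ".join(_COLUMNS) + " |\n")
                fh.write("|" + "---|" * len(_COLUMNS) + "\n")
                for r in provisional:
                    fh.write("| " + " | ".join(_record_row(r)) + " |\n")
            fh.write(
                f"\n**{summary.n_corroborated} of {summary.n_candidates} "
                "candidates corroborated by >=1 source.**\n"
            )
        else:
            raise ValueError(f"unknown format {fmt!r}")


def parse_report(path) -> list[EvidenceRecord]:
    """Parse a TSV report back into records (Mb-rounded coordinates)."""
    records: list[EvidenceRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _COLUMNS:
            raise ValueError("unrecognised report header")
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            vals = dict(zip(_COLUMNS, line.rstrip("\n").split("\t")))
            cand = BreakpointCandidate(
                kind=vals["type"],
                a_chrom=vals["a_chrom"],
                a_start_bp=int(round(float(vals["a_start_mb"]) * 1e6)),
                a_end_bp=int(round(float(vals["a_end_mb"]) * 1e6)),
                b_chrom=vals["b_chrom"],
                b_start_bp=int(round(float(vals["b_start_mb"]) * 1e6)),
                b_end_bp=int(round(float(vals["b_end_mb"]) * 1e6)),
            )
            records.append(
                EvidenceRecord(
                    candidate=cand,
                    linkage_support=vals["linkage_support"],
                    bng_support=vals["bng_support"],
                    ld_support=vals["ld_support"],
                )
            )
    return records
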