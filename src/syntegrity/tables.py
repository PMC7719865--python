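"""Curated baboon assembly-comparison tables shipped with the package.

Two small published tables from the Panubis1.0 / Panu_3.0 comparison are
bundled as worked-example inputs:

* the twelve large (>100 kb) syntenic differences where Hi-C supported
  Panubis1.0, with their per-source evidence labels (pedigree linkage,
  Bionano optical maps, LDhelmet rho anomalies), in Panu_3.0
  coordinates; and
* the twenty-one additional large inversion differences whose correct
  orientation could not be determined and which remain provisional.

These are *inputs* to the aggregation machinery (e.g. for
`summarize_support`), not outputs of this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .evidence import EvidenceRecord
from .synteny import BreakpointCandidate

__all__ = [
    "load_large_difference_table",
    "load_provisional_inversion_table",
    "published_support_records",
]


def _data(name: str):
    return resources.files("syntegrity.data").joinpath(name)


def load_large_difference_table() -> pd.DataFrame:
    """The 12 evidence-annotated large differences (Panu_3.0 coords, Mb)."""
    with resources.as_file(_data("panu3_large_differences.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_provisional_inversion_table() -> pd.DataFrame:
    """The 21 provisional large inversion differences."""
    with resources.as_file(_data("provisional_inversions.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def published_support_records() -> list[EvidenceRecord]:
    """The 12 large differences as EvidenceRecord objects.

    Coordinates are converted from the printed Mb values (2 decimals) to
    bp.  Candidate A coordinates are Panu_3.0, B coordinates Panu_2.0
    (where the linkage and LD evidence were computed).
    """
    df = load_large_difference_table()
    records = []
    for row in df.itertuples(index=False):
        b_lo = int(round(row.panu2_start_mb * 1e6))
        b_hi = int(round(row.panu2_end_mb * 1e6))
        cand = BreakpointCandidate(
            kind=row.type,
            a_chrom=row.panu3_chrom,
            a_start_bp=int(round(row.panu3_start_mb * 1e6)),
            a_end_bp=int(round(row.panu3_end_mb * 1e6)),
            b_chrom=row.panu3_chrom,
            b_start_bp=b_lo,
            b_end_bp=max(b_hi, b_lo + 1),
        )
        records.append(
            EvidenceRecord(
                candidate=cand,
                linkage_support=row.linkage_support,
                bng_support=row.bng_support,
                ld_support=row.ld_support,
            )
        )
    return records
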