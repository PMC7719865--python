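import numpy as np
import pytest

from syntegrity.crossovers import PedigreeSpec

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=10000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
"""


@pytest.fixture
def tiny_pedigree() -> PedigreeSpec:
    """Sire x two dams with three offspring (2 + 1)."""
    return PedigreeSpec(
        sire_id="SIRE",
        dam_ids=("DAM1", "DAM2"),
        offspring=(("KID1", "DAM1"), ("KID2", "DAM1"), ("KID3", "DAM2")),
    )


def make_vcf(path, samples, records, contigs=None):
    """Write a minimal VCF; records are (chrom, pos1, ref, alt, qual, calls)
    where calls is a list of 'GT:DP:GQ:AD' strings per sample."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in (contigs or {"chr1": 10_000_000}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(VCF_HEADER.split("\n", 2)[2])
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for chrom, pos, ref, alt, qual, calls in records:
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual}\t.\t.\tGT:DP:GQ:AD\t"
                + "\t".join(calls) + "\n"
            )
    return path


def call(gt, dp=30, gq=90, ad=None):
    """A passing FORMAT cell unless overridden."""
    if ad is None:
        n_alt = {"0/0": 0, "0/1": dp // 2, "1/1": dp}.get(gt, 0)
        ad = (dp - n_alt, n_alt)
    return f"{gt}:{dp}:{gq}:{ad[0]},{ad[1]}"


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
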