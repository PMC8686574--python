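import pytest

from mosaicscreen.core import (
    Genotype,
    SampleCall,
    ScreenConfig,
    TrioSiteCall,
    VariantKey,
)


@pytest.fixture
def cfg() -> ScreenConfig:
    return ScreenConfig()


def make_trio(
    pos=1000,
    proband=("het", 100, 47),
    mother=("ref_hom", 120, 0),
    father=("ref_hom", 110, 0),
    ref="A",
    alt="G",
    chrom="chr1",
    trio_id="trio1",
) -> TrioSiteCall:
    def call(member):
        gt, dp, ad = member
        return SampleCall(Genotype(gt), dp, ad)

    return TrioSiteCall(
        key=VariantKey(chrom, pos, ref, alt),
        proband=call(proband),
        mother=call(mother),
        father=call(father),
        trio_id=trio_id,
    )


@pytest.fixture
def clean_trio() -> TrioSiteCall:
    """A record that passes every screen predicate."""
    return make_trio()


def write_trio_vcf(path, rows, samples=("kid", "mom", "dad")):
    """Write a minimal trio VCF. rows: (chrom,pos,ref,alts,[(gt,ad_tuple,dp)])."""
    header = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
        "##contig=<ID=chr1>\n##contig=<ID=chrX>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
        + "\n"
    )
    lines = [header]
    for chrom, pos, ref, alts, calls in rows:
        fields = [chrom, str(pos), ".", ref, ",".join(alts), ".", "PASS", ".", "GT:AD:DP"]
        for gt, ad, dp in calls:
            fields.append(f"{gt}:{','.join(str(a) for a in ad)}:{dp}")
        lines.append("\t".join(fields) + "\n")
    with open(path, "w") as fh:
        fh.writelines(lines)
    return path
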