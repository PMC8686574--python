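"""Screen a small trio VCF for apparent de novo candidate variants.

Writes a four-record VCF for one trio, then runs the full screening cascade:
de novo genotype pattern, credible het VAF window (30-70%), minimum depth in
every trio member (20x), population-frequency rarity, and a repetitive-region
mask. Each record gets an auditable decision listing exactly which filters
it failed.
"""

import tempfile
from pathlib import Path

from mosaicscreen.core import PopulationFrequencies, ScreenConfig, VariantKey
from mosaicscreen.screen import RegionMask, read_trio_vcf, screen_trios

VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=248956422>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tkid\tmom\tdad
chr1\t10100\t.\tA\tG\t50\tPASS\t.\tGT:AD:DP\t0/1:53,47:100\t0/0:120,0:120\t0/0:110,0:110
chr1\t20200\t.\tC\tT\t50\tPASS\t.\tGT:AD:DP\t0/1:50,50:100\t0/1:60,55:115\t0/0:99,1:100
chr1\t30300\t.\tG\tA\t50\tPASS\t.\tGT:AD:DP\t0/1:70,10:80\t0/0:90,0:90\t0/0:85,0:85
chr1\t40400\t.\tT\tC\t50\tPASS\t.\tGT:AD:DP\t0/1:45,42:87\t0/0:70,0:70\t0/0:66,0:66
"""

with tempfile.TemporaryDirectory() as tmp:
    vcf_path = Path(tmp) / "trio.vcf"
    vcf_path.write_text(VCF)
    records = read_trio_vcf(vcf_path, proband="kid", mother="mom", father="dad",
                            trio_id="fam1")

    # site 40400 is common in the population; mask nothing here
    freqs = {VariantKey("chr1", 40400, "T", "C"): PopulationFrequencies(gnomad_af=1e-3)}
    decisions = screen_trios(records, freqs, mask=RegionMask(), cfg=ScreenConfig())

for d in decisions:
    verdict = "PASS" if d.passed else "fail: " + ",".join(d.failed_filters)
    print(f"{d.key.chrom}:{d.key.pos} {d.key.ref}>{d.key.alt} "
          f"proband VAF {d.proband_vaf:.2f}  ->  {verdict}")
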