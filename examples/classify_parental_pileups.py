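"""Re-genotype parents at candidate de novo sites from pileup allele counts.

A parent with a low-but-real alternate allele fraction (< 10%) that exceeds
what sequencing error explains (one-sided exact binomial test at error rate
0.5%) is a candidate mosaic; fractions in the het VAF window are
constitutional; the band in between is ambiguous and kept for manual review.
"""

from mosaicscreen.core import PileupCounts, ScreenConfig
from mosaicscreen.regenotype import classify_parent

cfg = ScreenConfig()
cases = {
    "typical mosaic (10/500, 2%)": PileupCounts(ref_fwd=245, ref_rev=245, alt_fwd=5, alt_rev=5),
    "single read at exome depth": PileupCounts(ref_fwd=15, ref_rev=14, alt_fwd=1),
    "no alternate evidence": PileupCounts(ref_fwd=60, ref_rev=60),
    "ambiguous 20% fraction": PileupCounts(ref_fwd=40, ref_rev=40, alt_fwd=10, alt_rev=10),
    "constitutional het": PileupCounts(ref_fwd=70, ref_rev=70, alt_fwd=55, alt_rev=55),
}

for label, pile in cases.items():
    c = classify_parent(pile, cfg)
    frac = "undefined" if pile.depth() == 0 else f"{c.alt_fraction:.3f}"
    print(f"{label:32s} alt {c.alt_count}/{c.depth} (frac {frac}, "
          f"error-test p {c.error_p:.3g})  ->  {c.status.value}")
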