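"""Quantify low-level mosaic VAFs by deep-amplicon counts and ddPCR.

Deep-amplicon sequencing gives a direct alt/depth ratio with an exact
Clopper-Pearson confidence interval; ddPCR infers per-channel template
concentrations from the fraction of negative droplets via Poisson statistics
(lambda = -ln(n_neg / n_total)) and reports the mutant fraction of total
template. Both apply a 0.5% limit of detection.
"""

from mosaicscreen.quantify import DropletCounts, amplicon_vaf_from_counts, ddpcr_vaf

# deep amplicon sequencing: 18,000 alternate reads out of 600,000
m = amplicon_vaf_from_counts(18_000, 600_000)
print(f"amplicon: VAF {100 * m.vaf:.2f}% "
      f"(95% CI {100 * m.ci_low:.2f}-{100 * m.ci_high:.2f}%), "
      f"detected={m.detected}")

# the same sample below the limit of detection
low = amplicon_vaf_from_counts(180, 600_000)
print(f"amplicon: VAF {100 * low.vaf:.2f}% -> detected={low.detected} (below 0.5% LoD)")

# a ddPCR well: droplet counts per fluorescence class
well = DropletCounts(n_mut_only=150, n_wt_only=7000, n_double_pos=120, n_neg=12730)
r = ddpcr_vaf(well)
print(f"ddPCR:    VAF {100 * r.vaf:.2f}% "
      f"(95% CI {100 * r.ci_low:.2f}-{100 * r.ci_high:.2f}%), "
      f"lambda mut {r.lambda_mut:.4f}, wt {r.lambda_wt:.4f}, "
      f"detected={r.detected}")
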