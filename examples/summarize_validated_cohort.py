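"""Summarize the bundled validated-parent and tissue-panel tables.

The package ships checksummed transcriptions of a 592-trio clinical cohort:
21 amplicon-validated mosaic parents with per-method VAFs, 10 enrolled
parents, and 5 multi-tissue panels. This script recomputes the headline
statistics from those tables.
"""

from mosaicscreen.report import (
    cohort_rates,
    germ_layer_summary,
    inheritance_breakdown,
    load_fixtures,
    parent_of_origin_counts,
    summarize_method,
    tissue_variance,
)

records, enrolled, panels = load_fixtures()
rates = cohort_rates()
print(f"flagged trios: {rates['flagged_rate_pct']}% of cohort; "
      f"validated: {rates['validated_rate_cohort_pct']}% of cohort "
      f"({rates['validated_rate_flagged_pct']}% of flagged)")

n_pat, n_mat = parent_of_origin_counts(records)
print(f"parental origin: {n_pat} paternal / {n_mat} maternal")
print(f"inheritance modes: {inheritance_breakdown(records, group_x_linked=True)}")

for method in ("es", "amplicon_ngs", "ddpcr"):
    stats = {s: summarize_method(records, method, s) for s in ("min", "median", "max")}
    print(f"{method:12s} VAF%: min {stats['min']}, median {stats['median']}, "
          f"max {stats['max']}")

m1 = next(p for p in panels if p.parent == "M1")
print(f"\nM1 cross-tissue amplicon-NGS sample variance: "
      f"{tissue_variance(m1, 'amplicon_ngs'):.1f}")
for layer, stats in germ_layer_summary(m1, "ddpcr").items():
    print(f"M1 ddPCR {layer}: max {stats['max']}%, mean {stats['mean']:.2f}%")
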