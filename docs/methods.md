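# Methods

Statistical model, parameter defaults and design rationale for
`mosaicscreen`.

## Problem

In a trio exome (proband, mother, father), a variant called heterozygous in
the child and homozygous-reference in both parents is *apparently de novo*.
A minority of such variants are actually present in one parent as low-level
somatic mosaicism — a postzygotic mutation carried by a few percent of the
parent's cells — hidden below the sensitivity of diploid genotype calling.
The package screens trio calls for such sites, re-genotypes the parents
directly from read counts, and quantifies confirmed mosaics with two
orthogonal assays.

## Screening cascade

Each trio record passes through five predicates; the decision records every
failed filter, so attrition is fully attributable and
`n_in = n_passed + n_failed` holds per filter.

| filter | rule | default |
|---|---|---|
| `denovo` | proband het/hemi, both parents hom-ref; missing genotypes fail | — |
| `het_window` | proband VAF in [30%, 70%] inclusive (hemizygous: ≥ 80%) | 0.30–0.70 |
| `depth` | minimum depth over **all three** members ≥ cutoff | 20× |
| `gnomad` | population AF strictly < cutoff (absent = 0 passes) | 10⁻⁴ |
| `internal_af` | internal cohort AF strictly < cutoff | 1.5 × 10⁻⁴ |
| `region_mask` | position outside repetitive/pseudogene BED intervals | — |

Design choices:

- **Depth applies to every trio member**, not the proband alone: the
  parental re-genotyping step downstream needs parental coverage just as the
  proband call does, so a site with an under-covered parent is unusable
  end-to-end.
- **Window bounds are inclusive** (a 30% VAF is a credible het); rarity
  cutoffs are strict (an allele exactly at the threshold is too common).
- BED masks are 0-based half-open on disk and converted once at load time;
  all internal positions are 1-based VCF-style.
- VAFs are fractions in [0, 1] internally; percent appears only at I/O
  boundaries. An undefined VAF (zero depth) is NaN, never 0.

## Parental re-genotyping

At each surviving site, the parent's pileup gives alternate count `k` out of
depth `n` (fraction `f = k/n`). Classification partitions all `(k, n)`:

- `f < 0.10` and `k ≥ 2` and `P(X ≥ k | n, e = 0.005) < α = 0.05` →
  **candidate_mosaic** (one-sided exact binomial test against the
  sequencing-error hypothesis);
- `f < 0.10` otherwise → **absent** (indistinguishable from error);
- `0.10 ≤ f < 0.30` → **ambiguous** — reported for manual review, never
  silently dropped;
- `f ≥ 0.30` → **constitutional_het** (fractions above 70% keep this status
  with a QC flag rather than creating a non-monotone band).

The partition is monotone in `k` at fixed depth
(absent → candidate_mosaic → ambiguous → constitutional_het), verified
exhaustively in tests against an independent brute-force enumeration of the
binomial tail. The error rate 0.5% is a conservative per-base substitution
rate for modern short-read exomes; α = 0.05 keeps the per-site false-flag
probability analytically bounded.

**Sensitivity definition.** The pipeline's recovery of a truly mosaic parent
counts any not-absent classification (candidate mosaic *or* ambiguous),
i.e. everything the cascade forwards for review — ambiguous calls model the
manual inspection step a clinical pipeline applies. The stricter
candidate-only rate is also computed and reported by
`scripts/acceptance.py`. Under the simulator's study conditions
(VAF ~ U(1%, 9%), depth ~ U(100, 300), e = 0.005), exact enumeration gives
an expected recovery of 0.93 and a candidate-only sensitivity of 0.86 among
parents whose expected alternate-read count reaches the 2-read minimum:
the losses are parents whose observed count falls below the error-test
detection threshold at their depth, and draws whose observed fraction
crosses the 10% boundary when the true VAF is near 9%.

## Quantification

### Deep-amplicon sequencing

VAF is the direct ratio `alt/depth` with an exact 95% Clopper–Pearson
interval computed from beta quantiles
(`lo = B(α/2; k, n−k+1)`, `hi = B(1−α/2; k+1, n−k)`, pinned to 0/1 at the
boundaries); tests cross-check it against an independent inversion of the
exact binomial test. At the assay's typical 10⁵–10⁶× depth the exact
interval's coverage is verified ≥ nominal by full enumeration rather than
Monte-Carlo. Base calls below a quality floor (Q20) are excluded from both
numerator and denominator.

Indel support is counted by walking CIGAR operations: an insertion or
deletion event is recorded at its reference anchor, normalized by
left-alignment through repeat runs (an indel is shifted left while the last
base of its inserted/deleted body equals the reference base at the current
anchor, which preserves the alternate haplotype sequence exactly), and
matched to the target allele by position, type, length and inserted
sequence. Reads that do not span the event plus a flank are excluded from
depth and tallied in a QC flag.

### Droplet digital PCR

Template is partitioned into ~20,000 droplets; each droplet is positive in
the mutant or wildtype channel iff it received ≥ 1 copy of that template.
Per-channel concentration follows from the negative fraction:
`λ = −ln(n_neg_channel / n_total)` copies per droplet, and
`VAF = λ_mut / (λ_mut + λ_wt)`. Channel λ confidence limits come from a
Clopper–Pearson interval on the negative-droplet fraction transformed
through the same log map; the VAF interval takes the conservative ratio
combination `[λm_lo/(λm_lo+λw_hi), λm_hi/(λm_hi+λw_lo)]`. The estimator is
symmetric under channel swap (VAF ↦ 1−VAF, interval reflected), a property
tested directly. A fully saturated channel (no negatives) is an error; a
well with no template in either channel is flagged, with undefined VAF.

### Limit of detection

Both assays use a 0.5% VAF limit of detection, applied inclusively
(a measurement exactly at 0.5% is detected). `lod_from_dilution` derives an
empirical LoD from a dilution series as the smallest level at which every
replicate is detected, requiring all higher levels fully detected as well.

**Cross-method concordance rule.** In the bundled tables, every variant
with an amplicon-NGS VAF *strictly below* 2% that was attempted by ddPCR is
not detected by ddPCR, while a measurement at exactly 2.0% is detected
(1.83% by ddPCR) — so the concordance check uses a strict 2% boundary:
NGS < 2% with ddPCR "ND" is concordant, both-numeric pairs report their
difference, and NT/DEG/NA states are excluded rather than counted either
way.

## Bundled data tables

`src/mosaicscreen/data/` ships TSV transcriptions of the clinical cohort —
21 validated mosaic parents (gene, variant, inheritance mode, parental
origin, per-method VAFs), 10 enrolled parents, 5 multi-tissue panels, the
cohort counting denominators and a tissue → germ-layer mapping — verified
at load time against a SHA-256 manifest. Non-numeric measurement states
(ND not detected, NT not tested, NA not attempted, DEG degraded DNA) are
preserved verbatim and never contribute to numeric statistics; tests verify
statistic invariance under injection of coded states.

Recomputed statistics follow the tables as transcribed. The tables'
internal inconsistencies with their surrounding prose are listed in
`data/errata.md` and deliberately not reconciled: the exome-VAF median
computes to 1.0 (prose prints 1.5), the ddPCR median to 3.8 (prose 3.7),
the autosomal-dominant count to 14 of 21 (prose 15), among others.

Two notational decisions made while transcribing: cross-tissue variance
uses the sample (n − 1) denominator, which reproduces the printed 14.1 for
parent M1 exactly; and the germ-layer mapping assigns blood/saliva to
mesoderm and hair/nail to ectoderm as stated, with buccal → ectoderm and
urine → endoderm chosen as the standard embryological assignments where the
source table leaves the mapping implicit.

## Simulators

All generators are pure functions of their parameters and a seed, and their
defaults are the study conditions — they are inputs to the analysis, not
tuning knobs:

- **Trio site**: proband alt reads ~ Binomial(depth, 0.5) for het
  (1 − e for hemizygous); the mosaic parent ~ Binomial(depth, p_eff) with
  p_eff = v(1−e) + (1−v)e; the clean parent ~ Binomial(depth, e).
- **Cohort**: 10% of trios carry one mosaic parent (mother/father
  equiprobable), VAF ~ U(1%, 9%), member depths ~ U{100..300}, e = 0.005.
- **Amplicon**: alt ~ Binomial(depth, v + e(1−v)) at 10⁵–10⁶× depth.
- **Droplets**: mutant/wildtype copies per droplet are independent
  Poisson(λv) and Poisson(λ(1−v)); droplets are assigned to the four
  channel classes by a single multinomial draw with the implied
  probabilities, distributionally identical to per-droplet sampling but
  O(1) in droplet count.

The simulators model binomial read sampling and Poisson partitioning only —
no PCR jackpot effects, strand bias, alignment artifacts or GC-dependent
coverage — which is sufficient for verifying estimator calibration and
cascade operating characteristics, not for benchmarking against real
sequencing error structure.

## Problem sizes and runtime

Test and acceptance problem sizes (200-trio cohorts, 25 replicates for
operating characteristics, 20,000-droplet wells, 100 coverage replicates,
exhaustive rule-oracle checks to depth 50) were chosen to give analytic or
better-than-1% Monte-Carlo resolution on every asserted bound while keeping
the full suite under a minute on one CPU.
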