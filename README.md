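# mosaicscreen

Detection and quantification of low-level parental somatic mosaicism from
trio exome sequencing.

A small fraction of apparently *de novo* pathogenic variants in a child are
in fact present at low level in one parent — a postzygotic (mosaic) mutation
carried by a minority of the parent's cells. Standard genotype callers miss
these because a 1–9% variant allele fraction (VAF) looks like sequencing
noise under a diploid genotype model. Finding them matters clinically: a
mosaic parent has a substantially elevated recurrence risk in future
pregnancies compared to a true germline *de novo* event.

`mosaicscreen` implements the complete screening cascade as a library plus a
thin command-line tool:

1. **Screen** trio VCFs for apparent *de novo* variants: proband
   het/hemizygous with both parents homozygous reference, proband VAF inside
   the credible het window (30–70% inclusive), ≥ 20× depth in every trio
   member, strict population rarity (GnomAD AF < 0.01%, internal cohort
   AF < 0.015%), and no overlap with a repetitive/pseudogene region mask.
2. **Re-genotype** each parent directly from pileup allele counts at the
   surviving sites. A parent with alternate-allele fraction below 10%,
   at least 2 alternate reads, and a one-sided exact binomial test rejecting
   the sequencing-error hypothesis (error rate 0.5%, α = 0.05) is a
   **candidate mosaic**; fractions in the het window are constitutional, and
   the band in between is flagged ambiguous — reported, never silently
   dropped.
3. **Quantify** candidate VAFs by deep-amplicon sequencing (direct allele
   counting with exact Clopper–Pearson confidence intervals, including a
   CIGAR-walk indel counter with left-alignment normalization) and by
   droplet digital PCR (per-channel template concentrations from the
   negative-droplet fraction via Poisson statistics), both with a 0.5%
   limit of detection.
4. **Report** summary statistics over a bundled, checksummed transcription
   of a 592-trio clinical cohort: 21 validated mosaic parents with
   per-method VAFs, multi-tissue panels, germ-layer rollups, and
   cross-method concordance.
5. **Simulate** every input — trio pileups under parental mosaicism, deep
   amplicon counts, Poisson droplet partitions — so the whole pipeline is
   testable without any external data.

## Worked example

Classify parental pileups at a candidate *de novo* site
(`examples/classify_parental_pileups.py`):

```python
from mosaicscreen.core import PileupCounts, ScreenConfig
from mosaicscreen.regenotype import classify_parent

cfg = ScreenConfig()
pile = PileupCounts(ref_fwd=245, ref_rev=245, alt_fwd=5, alt_rev=5)
c = classify_parent(pile, cfg)
print(c.status.value, c.alt_fraction, c.error_p)
```

Running the full example prints:

```
typical mosaic (10/500, 2%)      alt 10/500 (frac 0.020, error-test p 0.000264)  ->  candidate_mosaic
single read at exome depth       alt 1/30 (frac 0.033, error-test p 0.14)  ->  absent
no alternate evidence            alt 0/120 (frac 0.000, error-test p 1)  ->  absent
ambiguous 20% fraction           alt 20/100 (frac 0.200, error-test p 3.49e-26)  ->  ambiguous
constitutional het               alt 110/250 (frac 0.440, error-test p 5.81e-181)  ->  constitutional_het
```

The other scripts in `examples/` cover VCF screening, amplicon/ddPCR
quantification, the bundled cohort report, and sensitivity measurement on a
simulated cohort.

## Command line

```sh
mosaicscreen screen     --vcf trios.vcf --pedigree ped.tsv --freq af.tsv --mask repeats.bed --out candidates.tsv
mosaicscreen regenotype --candidates candidates.tsv --pileup pileups.tsv --out classifications.tsv
mosaicscreen amplicon   --counts amplicon_counts.tsv --out amplicon_vafs.tsv
mosaicscreen ddpcr      --droplets wells.tsv --out ddpcr_vafs.tsv
mosaicscreen report     --out report.json
mosaicscreen simulate cohort --n-trios 200 --seed 1 --out simdir/
mosaicscreen run-all    --config run.yaml
```

`run-all` chains screen → re-genotype from a YAML config and writes
candidates, classifications, a per-filter attrition log
(`n_in = n_passed + n_failed` for every filter) and a copy of the effective
configuration for provenance.

## Layout

- `src/mosaicscreen/` — library modules (`core`, `screen`, `regenotype`,
  `quantify`, `report`, `simulate`, `pipeline`, `cli`) and bundled data
  tables with a SHA-256 manifest
- `docs/methods.md` — statistical model, parameter defaults and design
  rationale
- `examples/` — runnable narrative scripts
- `tests/` — unit, property and acceptance tests
- `scripts/acceptance.py` — end-to-end recomputation of the headline numbers
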