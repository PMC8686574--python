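{
  "n_trios_initial": 783,
  "n_bam_unretrievable": 191,
  "n_trios_queried": 592,
  "n_flagged": 61,
  "n_amplicon_validated": 21,
  "n_ddpcr_tested": 7,
  "n_enrolled_parents": 10,
  "n_families_with_tissues": 9,
  "n_tissue_positive_parents": 5
}
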