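# Known internal inconsistencies in the transcribed source tables

The bundled tables are transcribed verbatim. The source publication's prose
disagrees with its own tables in a few places; the transcription keeps the
table values and records the discrepancies here rather than forcing
agreement. None of these quantities is used as a validated summary
statistic.

1. Exome-sequencing VAF median: the prose reports a median of 1.5% for the
   21 validated parents; the median of the transcribed exome VAF column is
   1%.
2. ddPCR blood VAF median: the prose reports 3.7%; the median of the seven
   transcribed ddPCR values (0.05, 1.83, 3.7, 3.8, 4.13, 4.5, 4.76) is 3.8.
3. Inheritance-mode breakdown: the prose reports 15/21 variants in
   autosomal-dominant (AD) trait genes; the transcribed table contains 14 AD
   rows (plus 4 AD/AR, 1 AR, 1 XL, 1 XLR).
4. The amplicon-NGS VAF range is quoted as 0.08–11.0% in the prose; the
   maximum of the transcribed NGS column is 9%.
5. The blood ddPCR value for parent M1 (USP7 c.238A>T) is 2.13% in the
   tissue panel but 4.13 in the 21-parent table.
6. The discussion attributes the COL11A1 c.3816+2dupT indel to parent M5
   and the CACNA1C saliva/urine ddPCR finding to the same subject id; the
   enrollment and tissue tables assign COL11A1 to M4 and CACNA1C to M5.
7. The prose states that amplicon-NGS blood VAFs "<= 2.0%" were not detected
   by ddPCR, but the table shows PIGA c.986T>C with NGS 2.0% detected by
   ddPCR at 1.83%; the discussion's strict phrasing ("below 2%") is
   consistent with every row and is the rule implemented here.
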