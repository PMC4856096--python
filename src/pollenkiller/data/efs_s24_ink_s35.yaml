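# Two independent pollen-killer pathways in an indica/japonica hybrid:
#   INK (activator, chr5) gates the killer S35 (chr1);
#   EFS (suppressor, chr2) gates the killer S24 (chr5).
# survival_s for S35 corresponds to k = 1/(1+s) = 0.89; the S24 value is a
# conservative choice inside its reported 90-99% transmission range.
# cM positions are illustrative (no published map distances).
loci:
  - {name: S35, chrom: chr1, pos_bp: 3060000, role: killer}
  - {name: S24, chrom: chr5, pos_bp: 1350000, role: killer}
  - {name: EFS, chrom: chr2, pos_bp: 24000000, role: partner}
  - {name: INK, chrom: chr5, pos_bp: 1700000, role: partner}
systems:
  - killer: S35
    partner: INK
    partner_mode: activator
    targeted_allele: J
    survival_s: 0.1236
    collateral_c: 0.0
  - killer: S24
    partner: EFS
    partner_mode: suppressor
    targeted_allele: J
    survival_s: 0.05
    collateral_c: 0.0
map:
  S35: 12.0
  S24: 5.4
  EFS: 96.0
  INK: 6.8
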