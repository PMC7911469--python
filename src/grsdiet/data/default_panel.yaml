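# Default 15-SNP panel: 5 vitamin D-related + 10 metabolic disease-related SNPs.
# Risk-allele orientations are PROVISIONAL placeholders taken from the cited
# GWAS literature (risk = vitamin D-lowering allele for the vitamin_d panel,
# obesity/T2D risk allele for the metabolic panel). They must be confirmed
# against the genotyping records before a production run; the pipeline
# refuses to score a provisional panel without --accept-panel.
- rsid: rs12785878
  gene: DHCR7
  risk_allele: T
  other_allele: G
  panel: vitamin_d
  provisional: true
- rsid: rs12794714
  gene: CYP2R1
  risk_allele: A
  other_allele: G
  panel: vitamin_d
  provisional: true
- rsid: rs6013897
  gene: CYP24A1
  risk_allele: A
  other_allele: T
  panel: vitamin_d
  provisional: true
- rsid: rs2282679
  gene: GC
  risk_allele: C
  other_allele: A
  panel: vitamin_d
  provisional: true
- rsid: rs1801725
  gene: CASR
  risk_allele: T
  other_allele: G
  panel: vitamin_d
  provisional: true
- rsid: rs8050136
  gene: FTO
  risk_allele: A
  other_allele: C
  panel: metabolic
  provisional: true
- rsid: rs9939609
  gene: FTO
  risk_allele: A
  other_allele: T
  panel: metabolic
  provisional: true
- rsid: rs10163409
  gene: FTO
  risk_allele: T
  other_allele: A
  panel: metabolic
  provisional: true
- rsid: rs12255372
  gene: TCF7L2
  risk_allele: T
  other_allele: G
  panel: metabolic
  provisional: true
- rsid: rs7903146
  gene: TCF7L2
  risk_allele: T
  other_allele: C
  panel: metabolic
  provisional: true
- rsid: rs17782313
  gene: MC4R
  risk_allele: C
  other_allele: T
  panel: metabolic
  provisional: true
- rsid: rs2229616
  gene: MC4R
  risk_allele: G
  other_allele: A
  panel: metabolic
  provisional: true
- rsid: rs2237895
  gene: KCNQ1
  risk_allele: C
  other_allele: A
  panel: metabolic
  provisional: true
- rsid: rs2237892
  gene: KCNQ1
  risk_allele: C
  other_allele: T
  panel: metabolic
  provisional: true
- rsid: rs10811661
  gene: CDKN2A/B
  risk_allele: T
  other_allele: C
  panel: metabolic
  provisional: true
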