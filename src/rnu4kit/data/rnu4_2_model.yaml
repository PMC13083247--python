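# Default structural model for RNU4-2 (U4 snRNA, transcript NR_003137.3 coordinates)
# and its paralog alignment to RNU4ATAC (U4atac, minor spliceosome).
# All coordinates are HGVS n.: 1-based, inclusive ends.
gene_id: RNU4-2
length: 144
regions:
  - {name: "Stem II", start: 3, end: 16, pm1_eligible: true}
  - {name: "5' stem loop", start: 20, end: 52, pm1_eligible: false}
  - {name: "Stem I", start: 56, end: 62, pm1_eligible: false}
  - {name: "t-loop", start: 63, end: 70, pm1_eligible: false}
  - {name: "Stem III", start: 75, end: 79, pm1_eligible: false}
  - {name: "3' stem loop", start: 85, end: 117, pm1_eligible: false}
  - {name: "Sm protein", start: 118, end: 126, pm1_eligible: true}
  - {name: "terminal stem loop", start: 127, end: 144, pm1_eligible: false}
# Kink-turn motif inside the 5' stem loop (SNU13/15.5k binding); PM1-eligible.
kturn_spans:
  - [27, 35]
  - [41, 46]
# Base-pairing partners within the 5' stem loop duplex. Only the 28<->45
# pair is encoded by default; the full duplex can be supplied in a user config.
pairing_pairs:
  - [28, 45]
# Regions in which heterozygous variants cause dominant ReNU syndrome.
renu_critical_regions: ["t-loop", "Stem III"]
paralog_alignment:
  source_gene: RNU4-2
  target_gene: RNU4ATAC
  target_length: 130
  # src_start, src_end, dst_start, dst_end (structurally identical segments)
  blocks:
    - [26, 52, 31, 57]
    - [115, 126, 113, 124]
thresholds:
  sge_significance: -0.302   # function score below this = significantly depleted
  inclusion_mean: -0.15      # per-individual mean score strict inclusion cutoff
  allele_frequency: 0.001    # PM2_supporting rarity threshold (0.1%)
  prevalence: 0.25           # phenotype term selection threshold for enrichment
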