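{
  "description": "Summary counts from a published 138-patient myeloid-neoplasm cohort comparing NGS-panel CNV/translocation detection with conventional cytogenetics. Per-alteration detail exists only for the discordant alterations (see the two TSV tables); concordant alterations are available as aggregate counts.",
  "n_alterations_total": 66,
  "n_both": 48,
  "n_both_unlisted": 47,
  "chromosome_counts": {
    "chr7": 16,
    "chr8": 12,
    "chr5": 11,
    "chr12": 8,
    "chr20": 7
  },
  "complete_cytogenetics_subset": {
    "n_patients": 121,
    "n_alterations": 64,
    "n_cyto_only": 10,
    "n_ngs_only": 7
  },
  "cohort_diseases": {
    "AML": 49,
    "MDS": 38,
    "MPN": 33,
    "MDS/MPN": 10,
    "MPAL": 5,
    "ALL": 3
  },
  "del12p_by_disease": {
    "AML": {"count": 4, "n_patients": 49},
    "MDS": {"count": 3, "n_patients": 38}
  }
}
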