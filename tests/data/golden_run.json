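{
  "seed": 20120,
  "result": {
    "peptide_id_rate": 0.9649390243902439,
    "protein_quant_rate": 0.8333333333333334,
    "qerr": 0.6424403804828365,
    "pct_markers_detected": 60.0,
    "peptide_missing_rate": 0.7940548780487805,
    "protein_missing_rate": 0.31666666666666665,
    "err_lda_observed": 0.19,
    "err_knn_observed": 0.33,
    "err_lda_original": 0.0,
    "err_knn_original": 0.0
  }
}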