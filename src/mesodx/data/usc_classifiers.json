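{
  "classifier_1": {
    "delta": 1.0,
    "rho": 0.7,
    "mistakes": 0,
    "average_genes": 18,
    "predictive_genes": [
      "ASS1", "BAP1", "CAV1", "CCNB1", "CD44", "CDH1", "EGR3", "FN1",
      "ITGA3", "KRT5", "LAMA3", "LGALS3", "MICAL2", "MMP9", "MYH11",
      "NME2", "NMU", "PAPPA", "PECAM1", "PKM", "RAD21", "TGFBR2"
    ]
  },
  "classifier_2": {
    "delta": 0.5,
    "rho": 0.7,
    "mistakes": 0,
    "average_genes": 34,
    "predictive_genes": [
      "ASS1", "BAP1", "CAV1", "CCNB1", "CD44", "CDH1", "CDH11", "COL4A2",
      "CTNNA1", "CXADR", "EEF2", "EGR3", "EIF4G1", "FANCI", "FN1",
      "GALNT7", "GLI2", "HEG1", "IFITM1", "ITGA3", "KRT5", "LAMA3",
      "LGALS3", "MAGED1", "MICAL2", "MMP9", "MYH11", "NME2", "NMU",
      "PAK4", "PAPPA", "PECAM1", "PKM", "PTGS2", "RAD21", "SDC1",
      "SMARCA4", "TGFBR2", "TOP2A", "VEGFA"
    ]
  }
}
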