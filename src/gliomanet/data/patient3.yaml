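patient_id: patient3
seed: 9
provenance: 'synthetic reconstruction: log-uniform [0.5,2] draw, seed 9; screened
  phenotype: combination non-responder'
multipliers:
  prod_EGF: 0.518773060633227
  prod_FGF: 0.9166837474609603
  prod_GCSF: 1.6480811695558704
  prod_GMCSF: 1.785682092264325
  prod_HGF: 0.5472638228540507
  prod_IL10: 1.1537225317794937
  prod_IL1b: 1.670752934280344
  prod_IL6: 0.7441340386278884
  prod_MIF: 1.5814444428413976
  prod_MMP9: 1.9542357102874262
  prod_PGE2: 1.7786223763051936
  prod_SCF: 0.5039149282928176
  prod_TGFb: 1.4692380516083348
  prod_TNFa: 1.3492421178176939
  prod_VEGF: 0.9793447096313374
  receptor_EGF: 1.4837208697295605
  receptor_FGF: 0.7744301254943802
  receptor_GCSF: 1.329300623347201
  receptor_GMCSF: 0.7569983949446467
  receptor_HGF: 1.3961916279975397
  receptor_IL10: 0.7368763414133148
  receptor_IL1b: 1.4795739762057467
  receptor_IL6: 1.9662973315852013
  receptor_MIF: 1.9622068015447502
  receptor_PGE2: 1.700224358107221
  receptor_SCF: 1.7722966484468676
  receptor_TGFb: 1.334605938289262
  receptor_TNFa: 1.0784757629282689
  receptor_VEGF: 1.7981039367694458
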