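patient_id: patient2
seed: 13
provenance: 'synthetic reconstruction: log-uniform [0.5,2] draw, seed 13; screened
  phenotype: modest combination response'
multipliers:
  prod_EGF: 1.7664027902344202
  prod_FGF: 1.958306999040344
  prod_GCSF: 1.1708720108696942
  prod_GMCSF: 0.5018268286550552
  prod_HGF: 1.5446952569030568
  prod_IL10: 1.539057142675441
  prod_IL1b: 1.6581737361958424
  prod_IL6: 1.6364902759179567
  prod_MIF: 0.9179962049681146
  prod_MMP9: 1.5533765041200849
  prod_PGE2: 1.8569456120423182
  prod_SCF: 0.5605115037214686
  prod_TGFb: 0.7184166656373491
  prod_TNFa: 0.5564789093964476
  prod_VEGF: 0.743597182161573
  receptor_EGF: 0.8811543530868275
  receptor_FGF: 1.0249115528705914
  receptor_GCSF: 0.5880781392260676
  receptor_GMCSF: 1.5454350662563037
  receptor_HGF: 0.997047966043233
  receptor_IL10: 0.7054219583680424
  receptor_IL1b: 1.4675120117477263
  receptor_IL6: 1.943229879430221
  receptor_MIF: 1.054593104069951
  receptor_PGE2: 1.389244419643502
  receptor_SCF: 1.9800287490673887
  receptor_TGFb: 0.5213250151743655
  receptor_TNFa: 1.1470714869445695
  receptor_VEGF: 1.9113481075906766
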