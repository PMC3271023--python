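patient_id: patient1
seed: 14
provenance: 'synthetic reconstruction: log-uniform [0.5,2] draw, seed 14; screened
  phenotype: responder to the VEGF/MIF/IL6/HGF combination'
multipliers:
  prod_EGF: 0.9555064438945079
  prod_FGF: 1.1056677127588859
  prod_GCSF: 1.438561446108458
  prod_GMCSF: 1.3496906376358577
  prod_HGF: 0.5460586573920363
  prod_IL10: 1.3245282470859205
  prod_IL1b: 1.5822380128046065
  prod_IL6: 0.8246725738041996
  prod_MIF: 1.3871408497412483
  prod_MMP9: 0.8690539766604466
  prod_PGE2: 1.0693442858515254
  prod_SCF: 1.2258241947376927
  prod_TGFb: 1.6474533037163481
  prod_TNFa: 1.2164145359734668
  prod_VEGF: 1.4070218377663357
  receptor_EGF: 1.0100068381584226
  receptor_FGF: 0.6865521689487152
  receptor_GCSF: 1.2314758719531893
  receptor_GMCSF: 1.9219469677502803
  receptor_HGF: 0.7565074365377145
  receptor_IL10: 0.9497775618525218
  receptor_IL1b: 1.7209769802468782
  receptor_IL6: 1.0738568993215403
  receptor_MIF: 0.8968443203173083
  receptor_PGE2: 1.2627608970317261
  receptor_SCF: 0.5218259021280799
  receptor_TGFb: 0.6188204743261475
  receptor_TNFa: 1.6732427563136036
  receptor_VEGF: 0.6226441090323372
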