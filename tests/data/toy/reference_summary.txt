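defchem 0.1.0 analysis summary
tree: tree.nwk (8 tips)
root treatment: fitzjohn; reporting threshold: 0.75

stage character best model (sequential LRT, alpha=0.05): ER
  ER: logL=-7.7635 params=1 AIC=17.5270
  SYM: logL=-7.1795 params=3 AIC=20.3591
  stage: logL=-7.0004 params=3 AIC=20.0008
  ARD: logL=-6.4841 params=6 AIC=24.9683

class character best model: ER
  ER: logL=-15.5673 params=1 AIC=33.1346

complexity BM fit: sigma2=0.053575 root estimate=1.5367
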