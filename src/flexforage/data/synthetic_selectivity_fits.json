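{
 "coef_xi": [
  -0.09232025036081182,
  0.46391725170898207,
  0.08308408755714662,
  -0.0935095233053931,
  -0.07370169927231746
 ],
 "coef_log_omega": [
  -0.6094501451853378,
  0.08224289776707668,
  -0.04545902805630352,
  0.0725569477142439,
  -0.012681763127657578
 ],
 "coef_alpha": [
  -7.450769701039027,
  -3.6967210756371847,
  -0.22455269801155672,
  5.326352545202892,
  0.17433471064611478
 ],
 "term_order": [
  "intercept",
  "log10_fish_mass",
  "temperature_C",
  "log10_resource",
  "temperature_C:log10_resource"
 ]
}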