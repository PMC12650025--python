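{
 "channel_names": [
  "Fp1",
  "Fp2",
  "F7",
  "F3",
  "Fz",
  "F4",
  "F8",
  "T3",
  "C3",
  "Cz",
  "C4",
  "T4",
  "T5",
  "P3",
  "Pz",
  "P4",
  "T6",
  "O1",
  "O2"
 ],
 "templates": [
  [
   0.09475898623883953,
   0.3028339268549581,
   -0.14837677928564963,
   -0.04220723178721645,
   0.10462971397205202,
   0.25983703684908466,
   0.39530290425969233,
   -0.33560474292922343,
   -0.16780237146461172,
   -1.1535483367598468e-18,
   0.16780237146461172,
   0.33560474292922343,
   -0.39530290425969233,
   -0.25983703684908466,
   -0.10462971397205202,
   0.04220723178721645,
   0.14837677928564963,
   -0.3028339268549581,
   -0.09475898623883953
  ],
  [
   0.3028339268549581,
   0.09475898623883953,
   0.39530290425969233,
   0.25983703684908466,
   0.10462971397205202,
   -0.04220723178721645,
   -0.14837677928564963,
   0.33560474292922343,
   0.16780237146461172,
   4.614193347039387e-18,
   -0.16780237146461172,
   -0.33560474292922343,
   0.14837677928564963,
   0.042207231787216457,
   -0.10462971397205202,
   -0.25983703684908466,
   -0.39530290425969233,
   -0.09475898623883953,
   -0.3028339268549581
  ],
  [
   -0.370236041748995,
   -0.370236041748995,
   -0.22993606803358638,
   -0.2026555175889236,
   -0.19486107460473423,
   -0.2026555175889236,
   -0.22993606803358638,
   -0.0,
   -0.0,
   -0.0,
   -0.0,
   -0.0,
   0.22993606803358638,
   0.2026555175889236,
   0.19486107460473423,
   0.2026555175889236,
   0.22993606803358638,
   0.370236041748995,
   0.370236041748995
  ],
  [
   0.03253048211889334,
   0.03253048211889334,
   -0.04791552655932344,
   0.22272936761010498,
   0.3382898439800835,
   0.22272936761010498,
   -0.04791552655932344,
   -0.17256382075458174,
   0.23074170403594338,
   0.3651768789661184,
   0.23074170403594338,
   -0.17256382075458174,
   -0.3017291368274941,
   -0.0009707634737062961,
   0.1231935640918034,
   -0.0009707634737062961,
   -0.3017291368274941,
   -0.37615244966883876,
   -0.37615244966883876
  ]
 ]
}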