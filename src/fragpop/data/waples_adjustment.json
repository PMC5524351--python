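{
  "comment": "Two-trait (age at maturity alpha, adult life span AL) regression coefficients for correcting LD-based effective-size estimates in species with overlapping generations (Waples, Antao & Luikart 2014, Genetics 197:769-780; two-trait rows of their Table 2). Both corrections are linear in log10(AL/alpha). Nb_adj = Nb_LD / (nb_intercept + nb_slope*log10(AL/alpha)); Ne = Nb_adj / (ne_intercept + ne_slope*log10(AL/alpha)).",
  "nb_intercept": 1.103,
  "nb_slope": -0.245,
  "ne_intercept": 0.485,
  "ne_slope": 0.758
}
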