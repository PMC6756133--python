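{
  "description": "Fixture logistic psychometric parameters for the simulated behavioral study: alpha is the speech reception threshold in dB SNR, beta the logistic spread in dB (slope at midpoint = 100/(4*beta) = 14.1 %/dB).",
  "alpha_db": -8.03,
  "beta_db": 1.773049645390071,
  "n_subjects": 19,
  "n_words_per_snr": 40,
  "snrs_db": [-12, -11, -10, -9, -8, -7, -6, -5, -4, -3]
}
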