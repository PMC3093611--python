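{
 "baseline_threshold": 1.0,
 "suppression_trailing": 0.49,
 "suppression_leading": 0.54,
 "prediction_amplitude": 0.52,
 "support_semisat_arcmin": 15.0,
 "projection_constant_arcmin": 25.0,
 "temporal_semisat_ms": 122.0,
 "interocular_transfer": 0.5,
 "transfer_suppression": false,
 "psychometric_slope": 10.0,
 "lapse_rate": 0.0,
 "guess_rate": 0.5,
 "rng_seed": 0
}
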