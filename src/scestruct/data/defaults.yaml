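# Default parameters of the internal structural predictors.
#
# Complexity: Wootton-Federhen window entropy (K2, bits) with the classic
# window of 12 residues and trigger/extension thresholds of 2.2/2.5 bits.
complexity:
  window_length: 12
  trigger_k: 2.2
  extension_k: 2.5
  alphabet_size: 20

# Disorder: per-residue propensity scale (TOP-IDP) smoothed by a moving
# average, mapped to [0, 1] by a logistic calibration.  The calibration
# midpoint sits halfway between the expected smoothed propensity of a
# uniform-composition (ordered) background (~0.027) and of the
# disorder-promoting residue set A,R,G,Q,S,P,E,K (~0.422), so that ordered
# compositions score < 0.5 and disorder-promoting compositions score > 0.5
# in expectation.
disorder:
  scale_file: top_idp_scale.tsv
  composition_window: 100
  smoothing_window: 21
  calibration_midpoint: 0.225
  calibration_steepness: 15.0
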