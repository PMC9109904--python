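{
 "regressors": ["1", "Ra", "Qa", "Rp", "CCT", "ACD", "Pup_X", "Pup_Y", "I_X", "I_Y"],
 "reverse_regressors": ["1", "Ra", "Qa", "Rp", "CCT", "ACD", "Pup_X", "Pup_Y", "CW_X", "CW_Y"],
 "forward": [
  [-0.6510, 0.0870, -0.0030, 0.0019, -0.0753, 0.0005, 1.0185, 0.0016, -0.1286, 0.0],
  [-0.0047, -0.0002, 0.0, 0.0009, 0.0, 0.0, 0.0, 1.0199, 0.0, -0.1284]
 ],
 "reverse": [
  [-5.0659, 0.6753, -0.0233, 0.0149, -0.5848, 0.0051, 7.9067, 0.0125, -7.7624, 0.0],
  [-0.0357, -0.0013, 0.0, 0.0071, 0.0, 0.0, 0.0, 7.9293, 0.0, -7.7738]
 ],
 "masks": [
  [1, 1, 1, 1, 1, 1, 1, 1, 1, 0],
  [1, 1, 0, 1, 0, 0, 0, 1, 0, 1]
 ],
 "provenance": {
  "version": "published_2022",
  "note": "Reference coefficients of the CW-chord / angle-alpha translation model fitted to a Monte-Carlo raytracing run over 8959 clinical anterior-segment measurements. Transcription notes: both intercepts carry a minus sign that is typographically lost in the source (verified by evaluating each model at the cohort mean biometry), and the second forward row is reconstructed from the cleanly printed reverse matrix via the exact inversion algebra.",
  "n": 8959
 }
}
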