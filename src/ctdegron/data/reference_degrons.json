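{
  "ADcon": "RMSAYGLAAA",
  "ssrA": "CAANDENYALAA",
  "ADpm_helix": "RMAAAALVS",
  "Euhalothece": "RMSAYGLREV"
}
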