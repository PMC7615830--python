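{
  "_comment": "SYNTHETIC/APPROXIMATE per-trial-type targets for the reversal task: mean value-related signal (approximate peak %BOLD units) for punish trials split by the following choice and for the following stay/switch trials, read approximately from published group-level figures. Stand-in values for the fitting pipeline, not measured data. Key qualitative structure: the signal falls from a punish trial to a stay trial and rises from a punish trial to a switch trial.",
  "punish_stay": 0.15,
  "stay": 0.05,
  "punish_switch": 0.05,
  "switch": 0.15
}
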