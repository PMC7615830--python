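{
  "_comment": "SYNTHETIC/APPROXIMATE per-condition behavioral targets for the contextual sensorimotor task: mean single-trial change in adaptation (arbitrary behavioral units) for each test-triplet exposure type, read approximately from published group-level figures. These are stand-in values for demonstrating the fitting pipeline, not measured data. Key qualitative structure: B+ largest, R+ substantial and larger than B-, R- smallest.",
  "B+": 1.0,
  "R+": 0.6,
  "B-": 0.45,
  "R-": 0.25
}
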