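# Neutral baseline value matrix: every square valued at 1.
effective_date: 1990-01-01
weights:
  A: 1.0
  B: 1.0
  C: 1.0
  D: 1.0
  E: 1.0
  F: 1.0
  G: 1.0
  H: 1.0
  I: 1.0
  J: 1.0
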