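name: wearable
terms:
  - apple watch
  - iwatch
  - applewatch
  - fitbit
  - fit bit
  - fit-bit
  - galaxy watch
  - samsung watch
  - google watch
  - kardia
  - alivecor
  - alive cor
  - wearable
  - smart watch
  - smartwatch
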