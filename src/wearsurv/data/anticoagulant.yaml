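name: anticoagulant
terms:
  - warfarin
  # direct oral anticoagulants
  - apixaban
  - dabigatran
  - rivaroxaban
  - edoxaban
  - betrixaban
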