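# Terms denoting atrial fibrillation. Duplicated surface forms collapse on
# normalization; punctuation dialects ("a.fib", "a - fib") are literal entries.
name: af
terms:
  - af
  - afib
  - a-fib
  - a.fib
  - arrhythmia
  - paf
  - atrial fibrillation
  - a. fib
  - a fib
  - atrial fib
  - atrial arrhythmia
  - irregular heartbeat
  - irregular hr
  - irregular rhythm
  - irregular pulse
  - irreg hr
  - irregular heart beat
  - irregular heart rhythm
  - irregular heart rate
  - irreg heart rhythm
  - irreg heart beat
  - irreg heart rate
  - abnormal ekg rhythm
  - paroxysmal atrial fibrillation
  - a - fib
  - pafib
  - abnormal heart rhythm
  - abnormal rhythm
  - abnormal hr
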