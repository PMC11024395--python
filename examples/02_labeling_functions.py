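"""Apply the eight labeling functions to example sentences.

Each LF votes POSITIVE when a sentence realizes one grammatical pattern of a
wearable AF prediagnosis, and abstains otherwise; negated AF mentions silence
every LF. The vote row prints as 8 columns (1 = POSITIVE, 0 = ABSTAIN).
"""

from wearsurv.weak_labeling import apply_lfs_to_note

sentences = [
    "AF noted on wearable",                   # LF2: AF + verb + prep + wearable
    "Wearable notified AF",                   # LF3: wearable + verb + AF
    "Got notification from wearable of AF",   # LF6 (and LF7)
    "Per wearable, patient had AF",           # LF8: wearable + subject + verb + AF
    "Apple Watch showed no afib",             # negated: everything abstains
]

print("lf:                                      1 2 3 4 5 6 7 8")
for text in sentences:
    row = apply_lfs_to_note(text)
    print(f"{text!r:41s}", " ".join(map(str, row)))

# LF1 (dictionary lookup: AF term + wearable term + event term anywhere) is
# the weakest condition and fires alongside every grammatical pattern.
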