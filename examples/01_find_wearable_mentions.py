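"""Find wearable-device mentions in a note and apply the action-vicinity rule.

The surveillance cohort starts from notes that mention a consumer wearable;
candidate notes are enriched by requiring an action term ("alerted",
"notified", ...) within 30 characters of the device mention, which filters
out boilerplate device recommendations.
"""

from wearsurv.lexicons import find_term_mentions, has_action_in_vicinity, load_lexicon

wearable = load_lexicon("wearable")

notes = [
    "Pt's Apple Watch alerted overnight for an irregular rhythm.",
    "We recommend the use of a wearable during meditation exercises.",
]

for text in notes:
    for m in find_term_mentions(text, wearable):
        relevant = has_action_in_vicinity(text, m, window=30)
        print(f"{text!r}")
        print(f"  device mention {text[m.start:m.end]!r} at [{m.start}, {m.end})"
              f" -> action within 30 chars: {relevant}")

# The first note keeps its candidate status (an action verb neighbors the
# device); the second is boilerplate and is filtered out.
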