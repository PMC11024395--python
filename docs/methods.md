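# Methods

## Problem setting

Consumer wearables can issue atrial-fibrillation (AF) *prediagnoses* —
automated notifications or user-initiated ECG interpretations — that may
drive downstream care. Because no structured EHR field records device
notifications, surveillance must classify free-text clinical notes as
containing a prediagnosis or not, then compare the identified patients
against wearable users without a prediagnosis. `wearsurv` implements that
pipeline end to end at desk scale, with a synthetic-EHR generator standing in
for a clinical corpus that cannot be distributed.

## Gazetteer matching and the candidate filter

Term dictionaries (wearables, AF terms, action terms, event nouns,
anticoagulants, rhythm-management drugs) ship as YAML and are matched on
normalized text (lowercased, whitespace-collapsed, with an offset map back to
the original string). Matching is longest-match, leftmost-first on token
boundaries, where a token boundary is an alphanumeric/non-alphanumeric
transition; punctuation dialects ("a.fib", "a - fib") are literal dictionary
entries. Candidate notes are enriched by the action-vicinity rule: an
action-term mention must start within 30 characters before the device
mention or end within 30 characters after it. The rule is evaluated on the
original (un-normalized) string so that it stays auditable against source
notes, and it is symmetric; both choices were genuinely open and are fixed
here. Action terms match on stems plus a table of irregular forms, so
"notified" and "saw" count.

## Sentence segmentation and coarse tagging

Sentences break at `.!?` followed by whitespace when the next non-space
character is uppercase or a digit; dotted medical abbreviations ("a.fib")
contain no whitespace after the period and never split, and abbreviation +
lowercase continuations ("a. fib") fail the capital test. Tokens carry one of
four part-of-speech classes — noun, verb, preposition, other — assigned from
closed lists (prepositions) and stem membership in the action/auxiliary verb
lists. The labeling-function patterns need only the verb/preposition
distinction, so no external tagger is required and the tagger's behavior is
fully deterministic.

## Labeling functions

Eight one-sided heuristics vote POSITIVE or ABSTAIN per note; none ever votes
negative (abstention is not evidence of absence at the heuristic level —
the label model handles that). LF1 is a note-scope dictionary conjunction:
an unnegated AF term, a wearable term and an action/event term anywhere in
the note. LF2–LF8 are sentence-scope ordered-slot patterns (for example
AF + verb + preposition + wearable) with at most G intervening tokens between
consecutive slots; G defaults to 5 because clinical prose inserts determiners
and modifiers ("AF was noted this morning on his Apple Watch"). A negation
trigger ("no", "not", "denies", "without", "negative for", "ruled out",
"never") preceding the AF mention within its sentence — with no intervening
"but"/"however" reset — silences every LF for that mention. Note-level votes
are the OR over sentences for LF2–LF8.

## Generative label model

Let y ~ Bernoulli(π) be the true note label. Each LF j has an accuracy
α_j and a propensity β_j; a one-sided LF can only *emit* POSITIVE, so
observationally

    P(vote⁺ | y=1) = β_j α_j,      P(vote⁺ | y=0) = β_j (1 − α_j),

with abstention the complement in each class, independently across LFs given
y. Would-be negative votes are unobservable and fold into abstention — the
standard data-programming generative model restricted to one-sided labelers.
A consequence worth stating: abstention carries weak negative evidence
(positive notes fire LFs more often), so an all-abstain note scores slightly
*below* the class prior. A parameterization in which abstains are exactly
uninformative is not a probability model for one-sided votes (its per-class
outcome probabilities do not sum to one) and EM under it degenerates, so this
package does not use it.

EM details: the E-step is Bayes' rule over the eight per-class Bernoulli
factors; the M-step re-estimates π from the mean posterior and the per-class
vote rates θ₁ⱼ = β_jα_j, θ₀ⱼ = β_j(1−α_j) from posterior-weighted counts,
mapping back via β = θ₁+θ₀, α = θ₁/(θ₁+θ₀). All parameters are clamped to
[10⁻³, 1−10⁻³]; convergence is a change in mean log-likelihood below 10⁻⁶
with at most 500 iterations; the log-likelihood is asserted non-decreasing
every iteration; non-convergence returns the last iterate flagged. Random
initializations draw accuracies from U(0.6, 0.9) — above one half, selecting
the basin where a POSITIVE vote evidences the positive class — and the prior
from U(0.1, 0.4). Model selection (`cv_select`) scores candidate fits from
different initializations by mean F1 over stratified k folds (default 10) of
a gold-labeled set, hardening posteriors at 0.5; ties break to the lowest
candidate index, and folds without positives are skipped with a warning.

## Noise-aware classifier

Training sets are stratified 1:2 positive:negative (the corpus is heavily
skewed negative), sampled uniformly without replacement from labels hardened
at 0.5, never including gold development/test notes. Each example's weight is
the label-model confidence (p for positives, 1−p for negatives); zero-weight
examples are dropped before fitting so they cannot perturb document
frequencies. The default model is logistic regression over word 1–3-gram
features with sublinear term frequency. Regularization defaults to C = 0.2:
the feature space is high-dimensional and sparse, and weaker penalties
memorize weak-label noise (hard-mode positives mislabeled negative) instead
of generalizing; the value was fixed from a small configuration grid
{0.2, 0.5, 1.0} on development corpora. The classifier exposes
text → probability with a 0.5 decision threshold; ROC and PR curves sweep
every distinct predicted probability. The interface deliberately matches what
a fine-tuned transformer would expose, and the fine-tuning settings such a
transformer would use are retained in `TRANSFORMER_PROVENANCE` as
configuration provenance only — no transformer is trained here.

## Synthetic EHR generator

The generator defines the study conditions. Positive notes realize one of the
eight LF patterns with surface forms sampled from the dictionaries and up to
`filler_cap` neutral tokens between slots (`filler_cap=0` is the
canonical-template limit; the default 2 stays within the LF gap G). Negative
notes are wearable-without-AF, negated-AF variants, meditation-boilerplate
distractors, and AF-without-wearable, in shares set by `negation_rate`
(0.10), `distractor_rate` (0.15) and `af_only_rate` (0.08). Prevalence
defaults to 0.18, the prevalence observed when this kind of wearable-enriched
note sample is manually labeled. Filler vocabulary contains no dictionary, verb, preposition or
negation tokens, so fillers can neither create nor destroy a pattern.

`hard=True` adds positives that the rules cannot reach, in two flavors:
pattern slots separated by more than G tokens (defeats the grammatical LFs
but not the note-scope dictionary LF, which is gap-insensitive), and
positives whose device surface form is a model name outside the gazetteer
("Versa", "Pixel Watch", drawn from a 40-name pool) — those defeat every LF
and are the channel through which a trained classifier can exceed the label
model's recall. The pool is wide so that no single out-of-vocabulary token
accumulates enough mislabeled-negative evidence to be memorized.

Structured tables are generated consistently with the note-level truth:
demographics with configurable race/ethnicity marginals, an 11.12% missing
race fraction mapped to "Undisclosed", and a small missing-sex fraction;
age-tilted comorbidity onsets; AF condition occurrences coded at concept
313217 or a generated descendant (two hierarchy levels, plus an unrelated
branch); prior-AF occurrences before the first note for a configurable share
of patients (and occasional AF codes in "other" settings, which must not
trigger the washout); anticoagulant / rhythm-drug exposures and cardioversion
procedures concentrated within 60 days of diagnosis, with a tail beyond the
window. The prediagnosis-to-diagnosis lag is geometric with mean 5 days.

What the generator does **not** emulate: real clinical language variation
(syntax beyond the templates, typos, section structure, copy-forward),
inter-annotator ambiguity, site-specific code sets, or correlated LF errors.
Passing tests therefore demonstrate the pipeline's correctness and its
qualitative behavior (exact recovery in the canonical limit, generalization
beyond rules under hard mode), not expected real-world operating points.

## Cohort analysis conventions

The index note is the oldest classifier-positive note, else the oldest
wearable note; date ties break to the lexicographically smallest note id.
Washout removes patients with an AF-coded ambulatory or inpatient occurrence
*strictly before* the index date; an occurrence on the index date is
retained. The diagnosis window is inclusive at both ends
(index ≤ d ≤ index + 60 days); both boundary conventions are configurable
and boundary-tested. CHA₂DS₂-VASc uses the standard point weights —
congestive heart failure 1, hypertension 1, age ≥ 75 2, diabetes 1,
stroke/TIA 2, vascular disease 1, age 65–74 1, female sex 1 — with mutually
exclusive age bands, condition components scored from code sets active on or
before the as-of date, and missing sex scoring zero with a flag. Ages are
completed years, birthday-inclusive.

Continuous variables use the one-tailed Welch t test (Welch–Satterthwaite
degrees of freedom) with the direction fixed per variable in configuration
(prediagnosis-group-greater by default for age and CHA₂DS₂-VASc);
categorical blocks use Pearson's χ² without continuity correction, df =
(r−1)(c−1), erroring on zero expected cells. P values are unadjusted for
multiplicity. Table percentages round half-up to two decimals computed on
exact integer ratios; the relative risk in "printed" mode is the ratio of the
two-decimal percentages, again rounded to two decimals, while "raw" mode
divides the unrounded risks. Stage "diagnosed" characterizes patients at the
index diagnosis date, counts only index prescriptions/procedures within 60
days of it, maps AF subtype from the diagnosis concept code, and omits
medication rows with zero prescriptions in both groups. Patients with missing
sex are excluded from every table.

## Problem sizes

The test suite and the acceptance script run the full pipeline at reduced
scale chosen for single-CPU execution: EM recovery on 5,000-note simulated
vote matrices (10 seeds), the canonical limit on 2,000 notes, and the
hard-mode corpus at roughly 30,000 notes from 15,000 patients with
training-set sizes 600 / 5,000 / 10,000 and 3 replicate seeds. Cohort
oracles use 500-patient panels.

## Known limitations

* The eight patterns and their lexicons are English-template-bound; the
  package does no general clinical NER, abbreviation disambiguation, spell
  correction, or cross-sentence coreference.
* The label model assumes conditional independence of LFs given the label
  and class-symmetric accuracies; correlated labeling functions would need a
  dependency-aware model.
* The default classifier is linear in n-gram features; it demonstrates the
  pipeline semantics, not transformer-level accuracy.
* The cohort stage estimates associations only — no causal adjustment,
  propensity matching, or survival analysis.
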