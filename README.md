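# wearsurv

**Weakly supervised EHR surveillance of consumer-wearable atrial-fibrillation
prediagnoses.**

Consumer wearables (Apple Watch, Fitbit, Kardia, ...) can notify their users
of a suspected atrial fibrillation (AF) — a *prediagnosis* that may trigger
follow-up care. Electronic health records have no billing code for "the
patient's watch went off", so postmarket surveillance of these devices has to
mine free-text clinical notes. `wearsurv` implements a complete,
desk-scale pipeline for that problem, aimed at clinical-NLP and
pharmaco/device-epidemiology researchers:

1. **Lexicons & filters** (`wearsurv.lexicons`, `wearsurv.corpus`) — term
   dictionaries for wearables, AF, action terms and medications; cohort note
   filters (wearable mention, age ≥ 22 at the note date, note date ≥
   2019-01-01); sentence segmentation with coarse POS tags; a 4096-token
   input budget.
2. **Labeling functions** (`wearsurv.weak_labeling`) — eight one-sided
   heuristics, one per grammatical pattern of a prediagnosis ("AF noted on
   wearable", "Per wearable, patient had AF", ...), with negation handling;
   they vote POSITIVE or ABSTAIN per note, forming an *n* × 8 vote matrix.
3. **Generative label model** (`wearsurv.label_model`) — per LF *j*, an
   accuracy α_j and propensity β_j; observationally
   P(vote⁺ | y=1) = β_j·α_j and P(vote⁺ | y=0) = β_j·(1−α_j) under
   conditional independence given the true label y ~ Bernoulli(π). Fit by EM
   (monotone log-likelihood, asserted); the E-step posterior
   p(y=1 | votes) is the note's probabilistic label. Model selection scores
   candidate fits by mean F1 over stratified k folds of a gold set.
4. **Noise-aware classifier** (`wearsurv.classifier`) — training sets
   stratified 1:2 positive:negative from hardened weak labels (never touching
   the gold test set), per-example weights equal to the label-model
   confidence, logistic regression over 1–3-gram sublinear-TF features
   behind an interface a transformer adapter could also satisfy; evaluation
   with precision/recall/F1/accuracy and full ROC / PR curves.
5. **Retrospective cohort study** (`wearsurv.cohort_analysis`) — index-note
   selection (oldest positive note, else oldest wearable note), washout of
   prior AF (concept 313217 + descendants, ambulatory/inpatient, strictly
   before index), AF diagnosis within an inclusive 60-day window,
   CHA₂DS₂-VASc scoring, one-tailed Welch *t* and χ² comparisons, relative
   risk, and the three two-group characteristics tables.
6. **Synthetic EHR** (`wearsurv.synthetic_ehr`) — a seeded generator of
   notes (known ground truth, prevalence 0.18, negated and boilerplate
   distractors, an optional `hard` mode whose positives evade the labeling
   functions) plus linked structured tables (demographics, conditions with a
   concept hierarchy, drugs, procedures), so every stage runs with no data
   access.

## Worked example

```python
>>> from wearsurv.weak_labeling import apply_lfs_to_note
>>> apply_lfs_to_note("Per wearable, patient had AF")
array([1, 0, 1, 0, 0, 0, 0, 1])
>>> apply_lfs_to_note("Apple Watch showed no afib")   # negation silences all LFs
array([0, 0, 0, 0, 0, 0, 0, 0])
```

End to end on synthetic data (`python examples/03_label_model.py`):

```
fitted class prior: 0.190 (generator prevalence 0.18)
per-LF accuracy:   [0.999 0.99  0.998 0.992 0.988 0.993 0.997 0.994]
per-LF propensity: [0.999 0.097 0.441 0.123 0.084 0.145 0.293 0.175]
vs ground truth: TP=230 FP=0 FN=0 (exact recovery in the canonical-template limit)
```

The fitted prior ≈ the generated prevalence, each LF's propensity reflects
how often its pattern occurs, and on gap-free template notes the combined
model reproduces the ground truth exactly — the regime in which weak
supervision replaces manual labeling outright. The cohort stage
(`python examples/05_cohort_study.py`) then prints the two-group tables and,
for one seeded synthetic cohort,

```
AF diagnosis within 60 days: 301/1060 (28.4%) with a prediagnosis vs 26/2330 (1.12%) without
relative risk 25.36; mean prediagnosis-to-diagnosis lag 4.75 days
```

i.e. patients whose notes carry a wearable prediagnosis are far more likely
to receive a clinician AF diagnosis within two months — the association the
surveillance system exists to measure.

Each script in `examples/` demonstrates one capability (mentions and the
action-vicinity rule, labeling functions, label model, classifier size sweep,
cohort study). A thin CLI covers the same stages from the shell:

```bash
wearsurv synth --out data --n-patients 1000 --seed 7
wearsurv label --notes data/notes.jsonl --out data/votes.csv
wearsurv labelmodel fit --votes data/votes.csv --params data/params.yaml
wearsurv labelmodel predict --votes data/votes.csv --params data/params.yaml --out data/labels.csv
wearsurv cohort --dir data --labels data/labels.csv --stage diagnosed
```

## Documentation

`docs/methods.md` describes the generative model, the synthetic-data design
and its limits, numerical choices, and known limitations.
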