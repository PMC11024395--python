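"""Seeded synthetic EHR: notes with known prediagnosis status plus structured tables.

The real note corpus behind this kind of surveillance is not distributable,
so every pipeline stage here runs against a generator that emulates its
relevant structure with known ground truth:

* **Positive notes** realize one of the eight grammatical patterns by which
  clinicians record a wearable AF prediagnosis ("AF noted on Apple Watch",
  "Per wearable, patient had a-fib", ...), with sampled surface forms and
  neutral filler tokens between pattern slots.
* **Negative notes** are wearable mentions without AF, negated-AF variants
  ("Apple Watch showed no afib"), meditation-boilerplate distractors, and AF
  without a wearable.
* **Structured tables** carry demographics (with a configurable missing
  race/ethnicity fraction), comorbidity onsets, AF condition occurrences
  coded at 313217 or a generated descendant, anticoagulant and
  rhythm-management drug exposures, cardioversion procedures, and a rooted
  concept-hierarchy edge list with two levels of descendants under 313217.

``hard=True`` additionally emits positives that no labeling function can
match (pattern gaps beyond the allowed token gap, or no action/event term at
all), creating irreducible label-model false negatives; a trained classifier
can still recover them from lexical evidence.

Everything is reproducible: one seed drives the whole dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import ClinicalNote, LabeledNote
from .weak_labeling import DEFAULT_GAP

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_notes",
    "generate_structured_ehr",
    "generate_dataset",
    "sample_gold_set",
    "AF_ROOT_CODE",
    "AF_HIERARCHY_EDGES",
    "AF_SUBTYPE_BY_CODE",
    "COMORBIDITY_CODES",
]

AF_ROOT_CODE = 313217
#: two levels of descendants under the AF root, plus an unrelated branch
AF_HIERARCHY_EDGES: tuple[tuple[int, int], ...] = (
    (AF_ROOT_CODE, 4154290),   # paroxysmal AF
    (AF_ROOT_CODE, 4141360),   # persistent AF
    (AF_ROOT_CODE, 4117112),   # chronic AF
    (4154290, 45768480),       # paroxysmal subtype, level 2
    (4141360, 45768481),       # persistent subtype, level 2
    (1000000, 1000001),        # unrelated concept branch
    (1000001, 1000002),
)
AF_SUBTYPE_BY_CODE: dict[int, str] = {
    AF_ROOT_CODE: "generic",
    4154290: "paroxysmal",
    45768480: "paroxysmal",
    4141360: "persistent",
    45768481: "persistent",
    4117112: "chronic",
}
COMORBIDITY_CODES: dict[str, int] = {
    "congestive_heart_failure": 444031,
    "hypertension": 320128,
    "diabetes": 201826,
    "vascular_disease": 321052,
    "stroke": 381316,
}

RACE_CATEGORIES = ("Asian", "Black", "Hispanic", "White", "Others")
RACE_WEIGHTS = (0.18, 0.035, 0.10, 0.66, 0.025)

# surface pools -------------------------------------------------------------

WEARABLE_SURFACES = ("Apple Watch", "apple watch", "Fitbit", "fit bit", "Kardia",
                     "AliveCor", "smartwatch", "smart watch", "Galaxy Watch", "wearable")
#: device model names absent from the wearable gazetteer (hard-mode positives);
#: a wide pool, the way real notes name devices by model rather than brand
OOV_WEARABLE_SURFACES = (
    "Versa", "Versa 2", "Versa 3", "Versa Lite", "Charge 3", "Charge 4",
    "Charge 5", "Sense", "Sense 2", "Luxe", "Inspire", "Inspire 2", "Ace 3",
    "Ionic", "Blaze", "Venu", "Venu 2", "Vivoactive 4", "Vivosmart 5",
    "Forerunner 245", "Fenix 6", "Lily", "Swim 2", "Pixel Watch",
    "Pixel Watch 2", "Ticwatch Pro", "Amazfit Bip", "Amazfit GTS", "Band 6",
    "Mi Band 5", "Watch GT 2", "Gear S3", "Active 2", "Versa 4", "Charge HR",
    "Surge", "Flex 2", "Alta HR", "Move ECG", "Scanwatch")
AF_SURFACES = ("AF", "afib", "a-fib", "a.fib", "atrial fibrillation",
               "irregular heart rhythm", "irregular pulse",
               "paroxysmal atrial fibrillation")
PAST_VERBS = ("noted", "showed", "detected", "recorded", "captured",
              "identified", "reported", "observed", "alerted", "notified",
              "registered")
GERUND_VERBS = ("showing", "recording", "capturing", "reading")
EVENT_NOUNS = ("notification", "alert", "alarm", "reading")
EVENT_FORMS = ("notified", "alerted", "notification", "alert", "warning")
SUBJECTS = ("patient", "pt", "he", "she")
PREPS_ON = ("on", "via", "per")
PREPS_FROM = ("from", "on", "via")

#: neutral filler vocabulary: no AF / wearable / action / event / negation /
#: preposition / verb tokens, so fillers never create or destroy a pattern
FILLER_WORDS = ("this", "morning", "last", "night", "earlier", "today",
                "again", "overnight", "yesterday", "briefly", "quietly",
                "routine", "mild", "transient", "intermittent", "episode",
                "evening", "afternoon", "twice")

#: filler sentences are action-free so the dictionary-lookup LF keeps its
#: note-level semantics
FILLER_SENTENCES = (
    "Vitals stable.",
    "Routine follow up in clinic.",
    "Medication list unchanged.",
    "Family history unremarkable.",
    "Sleep quality fair.",
    "Diet and exercise counseling provided previously.",
)

MEDITATION_BOILERPLATE = (
    "We recommend the use of a {wearable} during meditation and relaxation exercises.",
    "Consider a {wearable} for mindfulness and general wellness tracking.",
)

ANTICOAGULANT_WEIGHTS = {"apixaban": 0.50, "rivaroxaban": 0.20, "warfarin": 0.10,
                         "dabigatran": 0.10, "edoxaban": 0.05, "betrixaban": 0.05}
RHYTHM_WEIGHTS = {"metoprolol": 0.40, "diltiazem": 0.12, "flecainide": 0.08,
                  "atenolol": 0.06, "carvedilol": 0.05, "labetalol": 0.05,
                  "propafenone": 0.04, "verapamil": 0.04, "amlodipine": 0.06,
                  "digoxin": 0.05, "sotalol": 0.025, "dofetilide": 0.025}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    ``prevalence`` is the probability that a note carries a true
    prediagnosis (0.18, the prevalence a manually labeled sample of
    wearable-enriched notes exhibits);
    ``pattern_mix`` weights the eight positive templates; ``negation_rate``
    and ``distractor_rate`` set the shares of negated-AF and boilerplate
    notes among negatives. ``filler_cap`` bounds filler tokens between
    pattern slots (canonical corpora stay within the labeling-function token
    gap); ``hard`` adds positives outside any pattern's reach.
    """

    n_patients: int = 1000
    mean_notes_per_patient: float = 2.0
    prevalence: float = 0.18
    pattern_mix: tuple[float, ...] = (0.125,) * 8
    negation_rate: float = 0.10
    distractor_rate: float = 0.15
    af_only_rate: float = 0.08
    date_start: date = date(2019, 1, 1)
    date_end: date = date(2022, 12, 31)
    seed: int = 0
    filler_cap: int = 2
    hard: bool = False
    hard_fraction: float = 0.30
    missing_race_fraction: float = 0.1112
    missing_sex_fraction: float = 0.002
    prior_af_rate: float = 0.15
    diagnosis_rate_prediagnosed: float = 0.30
    diagnosis_rate_base: float = 0.016
    diagnosis_lag_mean_days: float = 5.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("prevalence", "negation_rate", "distractor_rate", "af_only_rate",
                     "missing_race_fraction", "hard_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if len(self.pattern_mix) != 8 or abs(sum(self.pattern_mix) - 1.0) > 1e-9:
            raise ValueError("pattern_mix must have 8 weights summing to 1")
        if self.date_end <= self.date_start:
            raise ValueError("empty date range")


@dataclass
class GroundTruth:
    """Per-note labels and per-patient true prediagnosis/diagnosis dates."""

    note_labels: dict[str, int]
    prediagnosis_date: dict[str, date | None]
    diagnosis_date: dict[str, date | None]

    def __post_init__(self) -> None:
        for pid, d in self.diagnosis_date.items():
            pre = self.prediagnosis_date.get(pid)
            if d is not None and pre is not None and d < pre:
                raise ValueError(f"diagnosis before prediagnosis for {pid}")


@dataclass
class SyntheticDataset:
    notes: list[ClinicalNote]
    truth: GroundTruth
    tables: dict[str, pd.DataFrame]


# --- note text construction --------------------------------------------------

def _filler(rng: np.random.Generator, max_tokens: int) -> list[str]:
    k = int(rng.integers(0, max_tokens + 1)) if max_tokens > 0 else 0
    return [str(rng.choice(FILLER_WORDS)) for _ in range(k)]


def _join_slots(rng: np.random.Generator, slots: Sequence[str], cap: int) -> str:
    parts: list[str] = []
    for i, slot in enumerate(slots):
        if i:
            parts.extend(_filler(rng, cap))
        parts.append(slot)
    sent = " ".join(parts)
    return sent[0].upper() + sent[1:] + "."


def _positive_sentence(rng: np.random.Generator, lf_id: int, cap: int) -> str:
    w = str(rng.choice(WEARABLE_SURFACES))
    af = str(rng.choice(AF_SURFACES))
    if lf_id == 1:
        return _join_slots(rng, [af, str(rng.choice(EVENT_NOUNS)), w], cap)
    if lf_id == 2:
        return _join_slots(rng, [af, str(rng.choice(PAST_VERBS)),
                                 str(rng.choice(PREPS_ON)), w], cap)
    if lf_id == 3:
        return _join_slots(rng, [w, str(rng.choice(PAST_VERBS)), af], cap)
    if lf_id == 4:
        return _join_slots(rng, [str(rng.choice(("observed", "noted", "checked", "saw"))),
                                 w, str(rng.choice(GERUND_VERBS)), af], cap)
    if lf_id == 5:
        return _join_slots(rng, [str(rng.choice(("received", "noted", "detected", "captured"))),
                                 af, str(rng.choice(PREPS_FROM)), w], cap)
    if lf_id == 6:
        return _join_slots(rng, [str(rng.choice(("got", "received", "had"))),
                                 str(rng.choice(EVENT_NOUNS)),
                                 str(rng.choice(PREPS_FROM)), w, "of", af], cap)
    if lf_id == 7:
        return _join_slots(rng, [str(rng.choice(EVENT_FORMS)),
                                 str(rng.choice(PREPS_ON)), w, "of", af], cap)
    if lf_id == 8:
        return _join_slots(rng, ["per", w + ",", str(rng.choice(SUBJECTS)),
                                 str(rng.choice(("had", "noticed", "reported", "saw"))),
                                 af], cap)
    raise ValueError(f"unknown pattern id {lf_id}")


def _hard_positive_sentence(rng: np.random.Generator, cap: int) -> str:
    """A true prediagnosis that evades labeling functions.

    Two flavors: (a) the wearable surface form is outside the gazetteer
    (device model names like "Versa"), so no LF sees a wearable mention at
    all, though the prose around it matches the canonical patterns; (b) the
    pattern slots are separated by more filler tokens than the allowed gap,
    which defeats the grammatical LFs (the note-level dictionary lookup can
    still fire on flavor b).
    """
    af = str(rng.choice(AF_SURFACES))
    if rng.random() < 0.5:
        w = str(rng.choice(OOV_WEARABLE_SURFACES))
        forms = (
            f"{af} {rng.choice(PAST_VERBS)} {rng.choice(PREPS_ON)} {w}",
            f"{w} {rng.choice(PAST_VERBS)} {af}",
            f"{rng.choice(('received', 'noted', 'detected'))} {af} "
            f"{rng.choice(PREPS_FROM)} {w}",
            f"per {w}, {rng.choice(SUBJECTS)} {rng.choice(('had', 'noticed', 'reported'))} {af}",
        )
        sent = str(rng.choice(forms))
    else:
        w = str(rng.choice(WEARABLE_SURFACES))
        long_gap = " ".join(str(rng.choice(FILLER_WORDS)) for _ in range(DEFAULT_GAP + 2))
        sent = f"{af} {long_gap} {rng.choice(PAST_VERBS)} {rng.choice(PREPS_ON)} {w}"
    return sent[0].upper() + sent[1:] + "."


def _negative_sentence(rng: np.random.Generator, kind: str) -> str:
    w = str(rng.choice(WEARABLE_SURFACES))
    af = str(rng.choice(AF_SURFACES))
    if kind == "wearable_only":
        forms = (
            f"Patient uses {w} daily to track steps.",
            f"{w} battery replaced at visit.",
            f"Discussed {w} activity data trends.",
            f"{w} sleep tracking reviewed with patient.",
        )
    elif kind == "negated":
        forms = (
            f"{w} showed no {af}.",
            f"Patient denies {af} episodes on {w}.",
            f"No {af} captured by {w} tracing.",
            f"Negative for {af} per {w} monitoring.",
        )
    elif kind == "distractor":
        forms = tuple(t.format(wearable=w) for t in MEDITATION_BOILERPLATE)
    elif kind == "af_only":
        forms = (
            f"History of {af}, currently stable on medication.",
            f"Longstanding {af} managed by cardiology.",
        )
    else:
        raise ValueError(kind)
    sent = str(rng.choice(forms))
    return sent[0].upper() + sent[1:]


def _note_text(rng: np.random.Generator, content: str) -> str:
    lead = [str(rng.choice(FILLER_SENTENCES)) for _ in range(int(rng.integers(0, 2)))]
    tail = [str(rng.choice(FILLER_SENTENCES)) for _ in range(int(rng.integers(0, 3)))]
    return " ".join(lead + [content] + tail)


def _random_date(rng: np.random.Generator, start: date, end: date) -> date:
    span = (end - start).days
    return start + timedelta(days=int(rng.integers(0, span + 1)))


def generate_notes(config: GeneratorConfig) -> tuple[list[ClinicalNote], GroundTruth]:
    """Generate the note corpus and its ground truth, reproducibly."""
    rng = np.random.default_rng(config.seed)
    notes: list[ClinicalNote] = []
    note_labels: dict[str, int] = {}
    prediag: dict[str, date | None] = {}
    diag: dict[str, date | None] = {}
    pattern_ids = np.arange(1, 9)
    counter = 0
    for p in range(config.n_patients):
        pid = f"P{p:05d}"
        n_notes = 1 + int(rng.poisson(max(config.mean_notes_per_patient - 1, 0)))
        patient_notes: list[tuple[date, str, int, bool]] = []  # date, text, label, wearable?
        for _ in range(n_notes):
            d = _random_date(rng, config.date_start, config.date_end)
            if rng.random() < config.prevalence:
                if config.hard and rng.random() < config.hard_fraction:
                    content = _hard_positive_sentence(rng, config.filler_cap)
                else:
                    lf_id = int(rng.choice(pattern_ids, p=config.pattern_mix))
                    content = _positive_sentence(rng, lf_id, config.filler_cap)
                patient_notes.append((d, _note_text(rng, content), 1, True))
            else:
                u = rng.random()
                if u < config.negation_rate:
                    kind = "negated"
                elif u < config.negation_rate + config.distractor_rate:
                    kind = "distractor"
                elif u < config.negation_rate + config.distractor_rate + config.af_only_rate:
                    kind = "af_only"
                else:
                    kind = "wearable_only"
                patient_notes.append(
                    (d, _note_text(rng, _negative_sentence(rng, kind)), 0,
                     kind != "af_only"))
        # every patient must carry at least one wearable-bearing note
        if not any(w for *_, w in patient_notes):
            d, _, _, _ = patient_notes[-1]
            patient_notes[-1] = (
                d, _note_text(rng, _negative_sentence(rng, "wearable_only")), 0, True)
        for d, text, label, _ in patient_notes:
            nid = f"N{counter:06d}"
            counter += 1
            notes.append(ClinicalNote(nid, pid, d, text))
            note_labels[nid] = label
        pos_dates = [d for d, _, label, _ in patient_notes if label == 1]
        prediag[pid] = min(pos_dates) if pos_dates else None
        # clinician-assigned AF diagnosis
        if prediag[pid] is not None:
            if rng.random() < config.diagnosis_rate_prediagnosed:
                if rng.random() < 0.05:
                    lag = 61 + int(rng.integers(0, 120))  # outside the 60-day window
                else:
                    lag = int(rng.geometric(1.0 / config.diagnosis_lag_mean_days))
                diag[pid] = prediag[pid] + timedelta(days=lag)
            else:
                diag[pid] = None
        else:
            if rng.random() < config.diagnosis_rate_base:
                first = min(d for d, *_ in patient_notes)
                diag[pid] = first + timedelta(days=int(rng.integers(0, 61)))
            else:
                diag[pid] = None
    return notes, GroundTruth(note_labels, prediag, diag)


def _weighted_choice(rng: np.random.Generator, weights: dict[str, float]) -> str:
    names = list(weights)
    w = np.array([weights[n] for n in names], dtype=float)
    return str(rng.choice(names, p=w / w.sum()))


def generate_structured_ehr(
    config: GeneratorConfig,
    truth: GroundTruth,
    notes: Sequence[ClinicalNote],
) -> dict[str, pd.DataFrame]:
    """Structured tables consistent with the note-level ground truth.

    Returns ``patients``, ``conditions``, ``drugs``, ``procedures`` and
    ``concept_edges`` DataFrames. Every AF diagnosis in the truth appears as
    a condition occurrence coded at 313217 or one of its generated
    descendants; prior-AF patients get an AF occurrence before their first
    note to exercise the washout rule.
    """
    rng = np.random.default_rng(config.seed + 1)
    first_note: dict[str, date] = {}
    for n in notes:
        if n.patient_id not in first_note or n.note_date < first_note[n.patient_id]:
            first_note[n.patient_id] = n.note_date
    pids = sorted(first_note)
    af_codes = list(AF_SUBTYPE_BY_CODE)
    af_code_weights = np.array([0.77, 0.12, 0.07, 0.015, 0.015, 0.01])

    patients_rows, cond_rows, drug_rows, proc_rows = [], [], [], []
    for pid in pids:
        age = int(rng.integers(18, 91))
        anchor = first_note[pid]
        birth = date(anchor.year - age, 1, 1) + timedelta(days=int(rng.integers(0, 365)))
        if birth > anchor:  # keep the completed age exact at the first note
            birth = birth.replace(year=birth.year - 1)
        sex = "missing" if rng.random() < config.missing_sex_fraction else (
            "male" if rng.random() < 0.45 else "female")
        if rng.random() < config.missing_race_fraction:
            race = "Undisclosed"
        else:
            race = str(rng.choice(RACE_CATEGORIES,
                                  p=np.array(RACE_WEIGHTS) / sum(RACE_WEIGHTS)))
        patients_rows.append({"patient_id": pid, "birth_date": birth.isoformat(),
                              "sex": sex, "race_ethnicity": race})

        age_factor = max(0.2, 1.0 + (age - 50) / 80.0)
        for name, code in COMORBIDITY_CODES.items():
            base = {"congestive_heart_failure": 0.07, "hypertension": 0.35,
                    "diabetes": 0.05, "vascular_disease": 0.08, "stroke": 0.04}[name]
            if rng.random() < min(base * age_factor, 0.95):
                onset = anchor - timedelta(days=int(rng.integers(30, 3000)))
                cond_rows.append({"patient_id": pid, "concept_code": code,
                                  "date": onset.isoformat(), "setting": "ambulatory"})

        if rng.random() < config.prior_af_rate:
            prior = anchor - timedelta(days=int(rng.integers(30, 1000)))
            code = int(rng.choice(af_codes, p=af_code_weights))
            setting = str(rng.choice(("ambulatory", "inpatient")))
            cond_rows.append({"patient_id": pid, "concept_code": code,
                              "date": prior.isoformat(), "setting": setting})
        elif rng.random() < 0.02:
            # AF coded outside ambulatory/inpatient care never triggers washout
            prior = anchor - timedelta(days=int(rng.integers(30, 1000)))
            cond_rows.append({"patient_id": pid, "concept_code": AF_ROOT_CODE,
                              "date": prior.isoformat(), "setting": "other"})

        d = truth.diagnosis_date.get(pid)
        if d is not None:
            code = int(rng.choice(af_codes, p=af_code_weights))
            setting = "ambulatory" if rng.random() < 0.7 else "inpatient"
            cond_rows.append({"patient_id": pid, "concept_code": code,
                              "date": d.isoformat(), "setting": setting})
            predi = truth.prediagnosis_date.get(pid)
            ac_rate = 0.35 if predi is not None else 0.25
            if rng.random() < ac_rate:
                lag = int(rng.integers(0, 61)) if rng.random() > 0.1 else int(rng.integers(61, 121))
                drug_rows.append({"patient_id": pid,
                                  "drug_name": _weighted_choice(rng, ANTICOAGULANT_WEIGHTS),
                                  "date": (d + timedelta(days=lag)).isoformat()})
            if rng.random() < 0.45:
                lag = int(rng.integers(0, 61))
                drug_rows.append({"patient_id": pid,
                                  "drug_name": _weighted_choice(rng, RHYTHM_WEIGHTS),
                                  "date": (d + timedelta(days=lag)).isoformat()})
            cv_rate = 0.09 if predi is not None else 0.05
            if rng.random() < cv_rate:
                proc_rows.append({"patient_id": pid, "procedure": "cardioversion",
                                  "date": (d + timedelta(days=int(rng.integers(0, 61)))).isoformat()})
        elif rng.random() < 0.03:
            drug_rows.append({"patient_id": pid,
                              "drug_name": _weighted_choice(rng, ANTICOAGULANT_WEIGHTS),
                              "date": (anchor + timedelta(days=int(rng.integers(0, 200)))).isoformat()})

    return {
        "patients": pd.DataFrame(patients_rows),
        "conditions": pd.DataFrame(cond_rows,
                                   columns=["patient_id", "concept_code", "date", "setting"]),
        "drugs": pd.DataFrame(drug_rows, columns=["patient_id", "drug_name", "date"]),
        "procedures": pd.DataFrame(proc_rows, columns=["patient_id", "procedure", "date"]),
        "concept_edges": pd.DataFrame(AF_HIERARCHY_EDGES, columns=["parent", "child"]),
    }


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Notes, ground truth, and structured tables from one seed."""
    notes, truth = generate_notes(config)
    tables = generate_structured_ehr(config, truth, notes)
    return SyntheticDataset(notes, truth, tables)


def sample_gold_set(
    notes: Sequence[ClinicalNote],
    truth: GroundTruth,
    n: int = 600,
    split: str = "test",
    seed: int = 0,
) -> list[LabeledNote]:
    """Sample a manually-labeled-set stand-in of ``n`` notes (one per patient)."""
    rng = np.random.default_rng(seed)
    by_patient: dict[str, list[ClinicalNote]] = {}
    for note in notes:
        by_patient.setdefault(note.patient_id, []).append(note)
    pids = sorted(by_patient)
    if len(pids) < n:
        raise ValueError(f"only {len(pids)} patients; cannot sample {n} gold notes")
    chosen = rng.choice(len(pids), n, replace=False)
    gold = []
    for i in sorted(chosen):
        cand = by_patient[pids[i]]
        note = cand[int(rng.integers(0, len(cand)))]
        gold.append(LabeledNote(note.note_id, truth.note_labels[note.note_id], split))
    return gold
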