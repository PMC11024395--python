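"""Clinical-note data model, cohort filters, segmentation and token budget.

The surveillance cohort is built from free-text notes: a note enters the
cohort when it mentions a wearable device, the patient was at least 22 years
old when it was written (the FDA age floor for the pertinent cardiovascular
algorithms), and it is dated on or after the first consumer AF-detection
feature release (2019-01-01 by default).

Segmentation is deterministic and protects dotted medical abbreviations
("a.fib") from being treated as sentence boundaries. Tokens carry a coarse
part-of-speech tag (noun / verb / preposition / other) — the only grammatical
distinction the labeling-function patterns need.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .lexicons import (
    TermLexicon,
    TermMention,
    find_term_mentions,
    load_lexicon,
    stems_of,
)

__all__ = [
    "ClinicalNote",
    "Token",
    "SentenceAnnotation",
    "LabeledNote",
    "filter_notes_for_cohort",
    "segment_and_tag",
    "select_candidate_sentences",
    "trim_to_token_budget",
    "count_tokens",
    "token_budget_proportion",
    "read_notes_jsonl",
    "write_notes_jsonl",
    "read_gold_csv",
    "write_gold_csv",
    "age_in_years",
]

PREPOSITIONS = frozenset(
    "on of from per by via with in at to for over after before during upon".split()
)
#: auxiliary / reporting verbs beyond the action lexicon
EXTRA_VERBS = frozenset(
    "be is are was were been being indicate reveal demonstrate suggest display "
    "deny denies use used uses wear wears wore worn sync synced".split()
)
PRONOUNS = frozenset("he she they it pt patient pts who".split())


def _parse_date(value) -> date:
    if isinstance(value, date) and not isinstance(value, datetime):
        return value
    if isinstance(value, datetime):
        return value.date()
    return date.fromisoformat(str(value))


@dataclass(frozen=True)
class ClinicalNote:
    """One clinical note flowing through filtering, labeling, classification."""

    note_id: str
    patient_id: str
    note_date: date
    text: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "note_date", _parse_date(self.note_date))


@dataclass(frozen=True)
class Token:
    surface: str
    pos: str  # NOUN | VERB | PREP | OTHER
    start: int
    end: int


@dataclass(frozen=True)
class SentenceAnnotation:
    """A sentence span with part-of-speech-tagged tokens (offsets into the note)."""

    start: int
    end: int
    tokens: tuple[Token, ...]

    def contains_span(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end

    def overlaps_span(self, start: int, end: int) -> bool:
        return start < self.end and self.start < end


@dataclass(frozen=True)
class LabeledNote:
    """A manually adjudicated note: gold label plus development/test split."""

    note_id: str
    gold_label: int  # 1 positive, 0 negative
    split: str       # "development" | "test"

    def __post_init__(self) -> None:
        if self.gold_label not in (0, 1):
            raise ValueError("gold_label must be 0 or 1")
        if self.split not in ("development", "test"):
            raise ValueError("split must be 'development' or 'test'")


def age_in_years(birth_date: date, as_of: date) -> int:
    """Completed years at ``as_of``, birthday-inclusive."""
    years = as_of.year - birth_date.year
    if (as_of.month, as_of.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def filter_notes_for_cohort(
    notes: Sequence[ClinicalNote],
    birth_dates: Mapping[str, date],
    cutoff_date: date = date(2019, 1, 1),
    min_age: int = 22,
    wearable_lexicon: TermLexicon | None = None,
) -> tuple[list[ClinicalNote], dict[str, int]]:
    """Retain wearable-bearing notes from adult patients on/after the cutoff.

    A note is kept iff it has at least one wearable-lexicon mention, the
    patient's completed age at the note date is >= ``min_age``, and
    ``note_date >= cutoff_date``. Returns the retained notes plus per-filter
    exclusion counts (each excluded note counted under its first failing
    rule, applied in the order: wearable mention, birth date known, age,
    date). A missing birth date is reported, not fatal.
    """
    lex = wearable_lexicon or load_lexicon("wearable")
    cutoff_date = _parse_date(cutoff_date)
    kept: list[ClinicalNote] = []
    excluded = {"no_wearable_mention": 0, "missing_birth_date": 0,
                "under_min_age": 0, "before_cutoff_date": 0}
    for note in notes:
        if not find_term_mentions(note.text, lex):
            excluded["no_wearable_mention"] += 1
            continue
        birth = birth_dates.get(note.patient_id)
        if birth is None:
            excluded["missing_birth_date"] += 1
            continue
        if age_in_years(_parse_date(birth), note.note_date) < min_age:
            excluded["under_min_age"] += 1
            continue
        if note.note_date < cutoff_date:
            excluded["before_cutoff_date"] += 1
            continue
        kept.append(note)
    return kept, excluded


# --- segmentation and tagging ----------------------------------------------

# a token is a dotted/hyphen-joined alphanumeric compound ("a.fib"), a plain
# alphanumeric run, or a single non-space symbol
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:\.[A-Za-z0-9]+)+|[A-Za-z0-9]+|[^\sA-Za-z0-9]")
_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s)")

_ACTION_STEMS: frozenset | None = None


def _action_stems() -> frozenset:
    global _ACTION_STEMS
    if _ACTION_STEMS is None:
        _ACTION_STEMS = frozenset(load_lexicon("action").terms)
    return _ACTION_STEMS


def _coarse_pos(surface: str) -> str:
    low = surface.lower()
    if not any(c.isalnum() for c in low):
        return "OTHER"
    if low in PREPOSITIONS:
        return "PREP"
    stems = stems_of(low)
    if low in EXTRA_VERBS or stems & EXTRA_VERBS or stems & _action_stems():
        return "VERB"
    if low[0].isdigit():
        return "OTHER"
    return "NOUN"


def _sentence_spans(text: str) -> list[tuple[int, int]]:
    """Deterministic sentence boundaries.

    A run of .!? followed by whitespace ends a sentence when the next
    non-space character is uppercase, a digit, or absent. Dotted
    abbreviations ("a.fib") have no whitespace after the internal period and
    abbreviations followed by a lowercase continuation ("a. fib") fail the
    capital test, so neither splits.
    """
    boundaries = []
    for m in _BOUNDARY_RE.finditer(text):
        rest = text[m.end():].lstrip()
        if not rest or rest[0].isupper() or rest[0].isdigit():
            boundaries.append(m.end())
    # newline runs also end sentences
    for m in re.finditer(r"\n\s*\n", text):
        boundaries.append(m.start())
    boundaries = sorted(set(boundaries))
    spans = []
    prev = 0
    for b in boundaries + [len(text)]:
        chunk = text[prev:b]
        stripped = chunk.strip()
        if stripped:
            s = prev + chunk.index(stripped[0])
            spans.append((s, s + len(chunk.strip())))
        prev = b
    return spans


def segment_and_tag(note: ClinicalNote | str) -> list[SentenceAnnotation]:
    """Split a note into sentences and tag tokens with coarse parts of speech."""
    text = note.text if isinstance(note, ClinicalNote) else note
    annotations = []
    for s, e in _sentence_spans(text):
        tokens = tuple(
            Token(m.group(0), _coarse_pos(m.group(0)), s + m.start(), s + m.end())
            for m in _TOKEN_RE.finditer(text[s:e])
        )
        annotations.append(SentenceAnnotation(s, e, tokens))
    return annotations


def select_candidate_sentences(
    annotations: Sequence[SentenceAnnotation],
    wearable_mentions: Sequence[TermMention],
) -> list[SentenceAnnotation]:
    """Sentences containing at least one wearable mention, in document order."""
    return [
        ann for ann in annotations
        if any(ann.overlaps_span(m.start, m.end) for m in wearable_mentions)
    ]


def count_tokens(text: str) -> int:
    return sum(1 for _ in _TOKEN_RE.finditer(text))


def trim_to_token_budget(text: str, budget: int = 4096) -> str:
    """Truncate at the tail on a token boundary so the count fits the budget.

    The budget mirrors the downstream classifier's maximum input length
    (4096 subword tokens by default); the tokenizer here is the package's
    own, so the budget is configurable.
    """
    if budget <= 0:
        raise ValueError("budget must be positive")
    spans = [m.span() for m in _TOKEN_RE.finditer(text)]
    if len(spans) <= budget:
        return text
    return text[: spans[budget - 1][1]]


def token_budget_proportion(notes: Iterable[ClinicalNote | str], budget: int = 4096) -> float:
    """Fraction of notes whose token count fits the budget."""
    texts = [(n.text if isinstance(n, ClinicalNote) else n) for n in notes]
    if not texts:
        raise ValueError("no notes supplied")
    fit = sum(1 for t in texts if count_tokens(t) <= budget)
    return fit / len(texts)


# --- I/O --------------------------------------------------------------------

def read_notes_jsonl(path: str | Path) -> list[ClinicalNote]:
    notes = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                rec = json.loads(line)
                notes.append(ClinicalNote(rec["note_id"], rec["patient_id"],
                                          rec["note_date"], rec["text"]))
    ids = [n.note_id for n in notes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate note_id in corpus")
    return notes


def write_notes_jsonl(notes: Iterable[ClinicalNote], path: str | Path) -> None:
    with open(path, "w") as fh:
        for n in notes:
            fh.write(json.dumps({"note_id": n.note_id, "patient_id": n.patient_id,
                                 "note_date": n.note_date.isoformat(), "text": n.text}) + "\n")


def read_gold_csv(path: str | Path) -> list[LabeledNote]:
    with open(path, newline="") as fh:
        return [LabeledNote(r["note_id"], int(r["label"]), r["split"])
                for r in csv.DictReader(fh)]


def write_gold_csv(gold: Iterable[LabeledNote], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["note_id", "label", "split"])
        for g in gold:
            w.writerow([g.note_id, g.gold_label, g.split])
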