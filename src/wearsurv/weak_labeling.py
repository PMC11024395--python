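"""The eight rule-based labeling functions (LFs) and the vote matrix.

Each LF is a one-sided heuristic that votes POSITIVE when a sentence realizes
one grammatical pattern by which clinicians describe a wearable-device AF
prediagnosis, and ABSTAINs otherwise:

====  =================================  ==================================
LF    pattern                            canonical example
====  =================================  ==================================
1     dictionary lookup (note level)     "AF" and "wearable" and "notification"
2     AF + verb + prep + wearable        "AF noted on wearable"
3     wearable + verb + AF               "Wearable notified AF"
4     verb + wearable + verb + AF        "Observed wearable showing AF"
5     verb + AF + prep + wearable        "Received AF from wearable"
6     verb + event + prep + wearable+AF  "Got notification from wearable of AF"
7     event + prep + wearable + AF       "Notified on wearable of AF"
8     wearable + subject + verb + AF     "Per wearable, patient had AF"
====  =================================  ==================================

A configurable gap of at most ``G`` intervening tokens (default 5) is allowed
between consecutive pattern slots, since clinical prose inserts determiners
and modifiers ("AF was noted this morning on his Apple Watch"). Negated AF
mentions ("no afib", "denies a-fib") never fire any LF. LFs emit
{POSITIVE, ABSTAIN} only — abstention is not a negative vote.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import ClinicalNote, LabeledNote, SentenceAnnotation, segment_and_tag
from .lexicons import (
    TermLexicon,
    TermMention,
    find_term_mentions,
    load_lexicon,
    stems_of,
)

__all__ = [
    "POSITIVE",
    "ABSTAIN",
    "N_LFS",
    "DEFAULT_GAP",
    "VoteMatrix",
    "detect_negation",
    "lf_apply",
    "apply_lfs_to_note",
    "assemble_vote_matrix",
    "lf_empirical_metrics",
    "NEGATION_TRIGGERS",
]

POSITIVE = 1
ABSTAIN = 0
N_LFS = 8
DEFAULT_GAP = 5

NEGATION_TRIGGERS = ("no", "not", "denies", "denied", "deny", "without", "never")
NEGATION_BIGRAMS = (("negative", "for"), ("ruled", "out"))
CONJUNCTION_RESETS = ("but", "however")

_SUBJECT_WORDS = frozenset(
    "patient pt pts he she they father mother son daughter man woman".split()
)

#: verb stems whose inflections also realize the "event" slot
#: ("Notified on wearable of AF")
EVENT_VERB_STEMS = frozenset(
    "notify alert alarm warn record report notice read".split()
)


@dataclass
class VoteMatrix:
    """n_notes x n_LF grid of {POSITIVE, ABSTAIN} votes; abstain is explicit."""

    note_ids: list[str]
    votes: np.ndarray  # shape (n_notes, N_LFS), values in {0, 1}

    def __post_init__(self) -> None:
        self.votes = np.asarray(self.votes, dtype=int)
        if self.votes.shape != (len(self.note_ids), N_LFS):
            raise ValueError(
                f"vote grid shape {self.votes.shape} != ({len(self.note_ids)}, {N_LFS})"
            )
        if not np.isin(self.votes, (POSITIVE, ABSTAIN)).all():
            raise ValueError("votes must be POSITIVE (1) or ABSTAIN (0)")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.votes, columns=[f"lf{j+1}" for j in range(N_LFS)])
        df.insert(0, "note_id", self.note_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "VoteMatrix":
        cols = [f"lf{j+1}" for j in range(N_LFS)]
        return cls(df["note_id"].astype(str).tolist(), df[cols].to_numpy())


def detect_negation(sentence: SentenceAnnotation, af_mention: TermMention) -> bool:
    """True iff a negation trigger precedes the AF mention within the sentence
    with no intervening conjunction reset ("but", "however")."""
    if not sentence.contains_span(af_mention.start, af_mention.end):
        raise ValueError("AF mention does not lie inside the sentence")
    negated = False
    prev = None
    for tok in sentence.tokens:
        if tok.start >= af_mention.start:
            break
        low = tok.surface.lower()
        if low in NEGATION_TRIGGERS:
            negated = True
        elif prev is not None and (prev, low) in NEGATION_BIGRAMS:
            negated = True
        elif low in CONJUNCTION_RESETS:
            negated = False
        prev = low
    return negated


# --- pattern machinery -------------------------------------------------------

def _mention_token_range(sentence: SentenceAnnotation, m: TermMention) -> tuple[int, int] | None:
    """Token index range [i, j] covered by a character-span mention."""
    idx = [k for k, t in enumerate(sentence.tokens) if t.start < m.end and m.start < t.end]
    if not idx:
        return None
    return idx[0], idx[-1]


def _slot_units(
    sentence: SentenceAnnotation,
    wearable_mentions: Sequence[TermMention],
    af_mentions: Sequence[TermMention],
    event_lexicon: TermLexicon,
) -> dict[str, list[tuple[int, int]]]:
    """Token-index ranges for each slot kind within one sentence."""
    units: dict[str, list[tuple[int, int]]] = {
        "WEARABLE": [], "AF": [], "VERB": [], "PREP": [], "EVENT": [], "SUBJ": [],
    }
    in_mention = set()
    for m in wearable_mentions:
        rng = _mention_token_range(sentence, m)
        if rng:
            units["WEARABLE"].append(rng)
            in_mention.update(range(rng[0], rng[1] + 1))
    for m in af_mentions:
        if detect_negation(sentence, m):
            continue
        rng = _mention_token_range(sentence, m)
        if rng:
            units["AF"].append(rng)
            in_mention.update(range(rng[0], rng[1] + 1))
    event_terms = set(event_lexicon.terms) | EVENT_VERB_STEMS
    for k, tok in enumerate(sentence.tokens):
        if k in in_mention:
            continue
        low = tok.surface.lower()
        if tok.pos == "VERB":
            units["VERB"].append((k, k))
        if tok.pos == "PREP":
            units["PREP"].append((k, k))
        if stems_of(low) & event_terms:
            units["EVENT"].append((k, k))
        if tok.pos == "NOUN" and low in _SUBJECT_WORDS:
            units["SUBJ"].append((k, k))
    return units


LF_PATTERNS: dict[int, tuple[str, ...]] = {
    2: ("AF", "VERB", "PREP", "WEARABLE"),
    3: ("WEARABLE", "VERB", "AF"),
    4: ("VERB", "WEARABLE", "VERB", "AF"),
    5: ("VERB", "AF", "PREP", "WEARABLE"),
    6: ("VERB", "EVENT", "PREP", "WEARABLE", "AF"),
    7: ("EVENT", "PREP", "WEARABLE", "AF"),
    8: ("WEARABLE", "SUBJ", "VERB", "AF"),
}


def _match_pattern(
    slots: tuple[str, ...],
    units: Mapping[str, list[tuple[int, int]]],
    gap: int,
) -> bool:
    """Ordered slot match with <= gap intervening tokens between slots."""

    def search(slot_idx: int, min_start: int, prev_end: int) -> bool:
        if slot_idx == len(slots):
            return True
        for s, e in units[slots[slot_idx]]:
            if s < min_start:
                continue
            if prev_end >= 0 and s - prev_end - 1 > gap:
                continue
            if search(slot_idx + 1, e + 1, e):
                return True
        return False

    return search(0, 0, -1)


def lf_apply(
    lf_id: int,
    sentence: SentenceAnnotation,
    wearable_mentions: Sequence[TermMention],
    af_mentions: Sequence[TermMention],
    event_lexicon: TermLexicon | None = None,
    gap: int = DEFAULT_GAP,
) -> int:
    """Vote of one LF on one sentence: POSITIVE or ABSTAIN.

    LF1, applied at sentence scope, requires an unnegated AF term, a wearable
    term, and a notification-event term (action verb or event noun) with no
    ordering constraint; at note scope :func:`apply_lfs_to_note` evaluates it
    across the whole note. LF2-LF8 require their ordered slot pattern.
    """
    if lf_id not in range(1, N_LFS + 1):
        raise ValueError(f"unknown labeling function id {lf_id}")
    event_lexicon = event_lexicon or load_lexicon("event")
    units = _slot_units(sentence, wearable_mentions, af_mentions, event_lexicon)
    if lf_id == 1:
        has_event = bool(units["EVENT"]) or bool(units["VERB"])
        return POSITIVE if units["AF"] and units["WEARABLE"] and has_event else ABSTAIN
    if not units["AF"]:
        return ABSTAIN
    return POSITIVE if _match_pattern(LF_PATTERNS[lf_id], units, gap) else ABSTAIN


def apply_lfs_to_note(
    note: ClinicalNote | str,
    wearable_lexicon: TermLexicon | None = None,
    af_lexicon: TermLexicon | None = None,
    action_lexicon: TermLexicon | None = None,
    event_lexicon: TermLexicon | None = None,
    gap: int = DEFAULT_GAP,
) -> np.ndarray:
    """One vote row for a note.

    LF2-LF8: OR over candidate (wearable-bearing) sentences. LF1: POSITIVE
    iff the note contains an unnegated AF term, a wearable term, and an
    action/event term anywhere.
    """
    text = note.text if isinstance(note, ClinicalNote) else note
    wearable_lexicon = wearable_lexicon or load_lexicon("wearable")
    af_lexicon = af_lexicon or load_lexicon("af")
    action_lexicon = action_lexicon or load_lexicon("action")
    event_lexicon = event_lexicon or load_lexicon("event")

    wearables = find_term_mentions(text, wearable_lexicon)
    afs = find_term_mentions(text, af_lexicon)
    annotations = segment_and_tag(text)
    row = np.zeros(N_LFS, dtype=int)

    # note-level state for LF1
    has_wearable = bool(wearables)
    has_unnegated_af = False
    has_event = False
    action_stems = set(action_lexicon.terms) | set(event_lexicon.terms)

    for ann in annotations:
        sent_wearables = [m for m in wearables if ann.overlaps_span(m.start, m.end)]
        sent_afs = [m for m in afs if ann.contains_span(m.start, m.end)]
        mention_spans = [(m.start, m.end) for m in sent_wearables + sent_afs]
        for m in sent_afs:
            if not detect_negation(ann, m):
                has_unnegated_af = True
        for tok in ann.tokens:
            inside = any(s <= tok.start and tok.end <= e for s, e in mention_spans)
            if not inside and stems_of(tok.surface.lower()) & action_stems:
                has_event = True
        if not sent_wearables:
            continue
        for lf_id in range(2, N_LFS + 1):
            if row[lf_id - 1] == ABSTAIN:
                row[lf_id - 1] = lf_apply(lf_id, ann, sent_wearables, sent_afs,
                                          event_lexicon, gap)
    if has_wearable and has_unnegated_af and has_event:
        row[0] = POSITIVE
    return row


def assemble_vote_matrix(
    notes: Sequence[ClinicalNote],
    gap: int = DEFAULT_GAP,
    **lexicons,
) -> VoteMatrix:
    """Apply all LFs to every note; rows follow the input order."""
    rows = [apply_lfs_to_note(n, gap=gap, **lexicons) for n in notes]
    votes = np.vstack(rows) if rows else np.zeros((0, N_LFS), dtype=int)
    return VoteMatrix([n.note_id for n in notes], votes)


def lf_empirical_metrics(matrix: VoteMatrix, gold: Sequence[LabeledNote]) -> pd.DataFrame:
    """Per-LF precision/recall/F1/accuracy against gold labels.

    ABSTAIN scores as a negative prediction, so accuracy is defined for
    one-sided LFs. Formulas: precision TP/(TP+FP), recall TP/(TP+FN),
    F1 2PR/(P+R), accuracy (TP+TN)/n.
    """
    if not gold:
        raise ValueError("empty gold set")
    index = {nid: i for i, nid in enumerate(matrix.note_ids)}
    missing = [g.note_id for g in gold if g.note_id not in index]
    if missing:
        raise KeyError(f"gold notes absent from vote matrix: {missing[:5]}")
    y = np.array([g.gold_label for g in gold])
    rows = []
    for j in range(N_LFS):
        pred = np.array([matrix.votes[index[g.note_id], j] for g in gold])
        tp = int(((pred == 1) & (y == 1)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        tn = int(((pred == 0) & (y == 0)).sum())
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        rows.append({"lf": f"lf{j+1}", "precision": precision, "recall": recall,
                     "f1": f1, "accuracy": (tp + tn) / len(y)})
    return pd.DataFrame(rows).set_index("lf")
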