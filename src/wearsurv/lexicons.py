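"""Term dictionaries and normalized gazetteer matching.

Clinical notes mention consumer wearables and atrial fibrillation (AF) in a
mess of surface forms ("Apple Watch", "fit-bit", "a.fib", "irreg HR"). This
module houses the term dictionaries used throughout the pipeline — wearable
devices, action terms, AF terms, anticoagulants, rhythm-management drugs and
notification-event nouns — and provides:

* whitespace/case normalization with an offset map back to the raw note,
* longest-match, token-boundary gazetteer matching (``find_term_mentions``),
* the action-term vicinity rule used to enrich candidate notes
  (``has_action_in_vicinity``), with stem-aware matching so inflections
  ("notified", "alerts") count.

Built-in lexicons ship as YAML files in :mod:`wearsurv.data`; user extension
files merge additively via :func:`load_lexicon`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

import yaml

__all__ = [
    "TermLexicon",
    "TermMention",
    "normalize_text",
    "find_term_mentions",
    "has_action_in_vicinity",
    "load_lexicon",
    "builtin_lexicon_names",
    "stems_of",
]

BUILTIN_LEXICONS = ("wearable", "action", "af", "anticoagulant", "rhythm", "event")

#: irregular inflection -> base form, for stem-aware action matching
IRREGULAR_FORMS = {
    "saw": "see",
    "seen": "see",
    "got": "get",
    "gotten": "get",
    "had": "have",
    "has": "have",
    "gave": "give",
    "given": "give",
    "told": "tell",
    "shown": "show",
    "showed": "show",
    "read": "read",
}


def _normalize_term(term: str) -> str:
    return re.sub(r"\s+", " ", term.strip().lower())


@dataclass(frozen=True)
class TermLexicon:
    """A named set of lowercase surface strings matched as whole-token spans."""

    name: str
    terms: tuple[str, ...]
    match_policy: str = "longest"  # longest-match, leftmost-first

    def __post_init__(self) -> None:
        normalized = []
        seen = set()
        for t in self.terms:
            nt = _normalize_term(t)
            if not nt:
                raise ValueError(f"lexicon {self.name!r} contains an empty term")
            if nt not in seen:
                seen.add(nt)
                normalized.append(nt)
        object.__setattr__(self, "terms", tuple(normalized))

    def __contains__(self, term: str) -> bool:
        return _normalize_term(term) in set(self.terms)

    def merged_with(self, extra_terms: Iterable[str]) -> "TermLexicon":
        """Additive merge of user-supplied terms (duplicates collapse)."""
        return TermLexicon(self.name, self.terms + tuple(extra_terms), self.match_policy)


@dataclass(frozen=True)
class TermMention:
    """A lexicon term located in a note, with offsets into the *original* text."""

    lexicon_name: str
    term: str
    start: int  # 0-based, inclusive
    end: int    # 0-based, exclusive

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid mention span [{self.start}, {self.end})")


def load_lexicon(name: str, extra_terms: Sequence[str] = ()) -> TermLexicon:
    """Load a built-in lexicon by name, optionally merging extension terms."""
    if name not in BUILTIN_LEXICONS:
        raise KeyError(f"unknown lexicon {name!r}; built-ins: {BUILTIN_LEXICONS}")
    path = resources.files("wearsurv.data").joinpath(f"{name}.yaml")
    payload = yaml.safe_load(path.read_text())
    lex = TermLexicon(payload["name"], tuple(payload["terms"]))
    if extra_terms:
        lex = lex.merged_with(extra_terms)
    return lex


def builtin_lexicon_names() -> tuple[str, ...]:
    return BUILTIN_LEXICONS


def _lower_char(c: str) -> str:
    low = c.lower()
    return low if len(low) == 1 else c


def normalize_text(text: str) -> tuple[str, list[int]]:
    """Lowercase and collapse whitespace; return (normalized, offset map).

    ``offset_map[i]`` is the index in the original string of the character
    that produced normalized character ``i``. Runs of whitespace collapse to
    a single space mapped to the first whitespace character of the run;
    leading/trailing whitespace is dropped. Normalization is idempotent.
    """
    out: list[str] = []
    offsets: list[int] = []
    pending_space = -1  # original index of a pending collapsed space
    for i, c in enumerate(text):
        if c.isspace():
            if pending_space < 0:
                pending_space = i
            continue
        if pending_space >= 0 and out:
            out.append(" ")
            offsets.append(pending_space)
        pending_space = -1
        out.append(_lower_char(c))
        offsets.append(i)
    return "".join(out), offsets


def _is_token_char(c: str) -> bool:
    return c.isalnum()


def _on_token_boundary(norm: str, start: int, end: int) -> bool:
    # a match edge sits on a token boundary unless an alphanumeric character
    # continues outside the matched span
    if start > 0 and _is_token_char(norm[start - 1]) and _is_token_char(norm[start]):
        return False
    if end < len(norm) and _is_token_char(norm[end - 1]) and _is_token_char(norm[end]):
        return False
    return True


def find_term_mentions(text: str, lexicon: TermLexicon) -> list[TermMention]:
    """All non-overlapping longest lexicon matches on token boundaries.

    Matching runs on the normalized text; reported offsets refer to the
    original string. Overlaps resolve leftmost-first, longest-at-a-start.
    Deterministic and independent of lexicon term order.
    """
    if not lexicon.terms:
        raise ValueError("lexicon is empty")
    norm, offsets = normalize_text(text)
    if not norm:
        return []
    candidates: list[tuple[int, int, str]] = []  # (start, -len, term)
    for term in lexicon.terms:
        pos = norm.find(term)
        while pos >= 0:
            end = pos + len(term)
            if _on_token_boundary(norm, pos, end):
                candidates.append((pos, -len(term), term))
            pos = norm.find(term, pos + 1)
    candidates.sort()
    mentions: list[TermMention] = []
    taken_until = -1
    for start, neg_len, term in candidates:
        end = start - neg_len
        if start <= taken_until:
            continue
        taken_until = end - 1
        orig_start = offsets[start]
        orig_end = offsets[end - 1] + 1
        mentions.append(TermMention(lexicon.name, term, orig_start, orig_end))
    return mentions


# --- stem-aware action matching -------------------------------------------

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")


@lru_cache(maxsize=65536)
def stems_of(token: str) -> frozenset[str]:
    """Candidate base forms of a (lowercased) token: identity, irregular
    table lookup, and light suffix stripping (s/es/ed/d/ing, ied/ies -> y,
    consonant doubling)."""
    token = token.lower()
    stems = {token}
    if token in IRREGULAR_FORMS:
        stems.add(IRREGULAR_FORMS[token])
    for suffix, repl in (("ies", "y"), ("ied", "y"), ("ing", ""), ("ed", ""),
                         ("es", ""), ("s", ""), ("d", ""), ("e", "")):
        if token.endswith(suffix) and len(token) - len(suffix) >= 2:
            base = token[: len(token) - len(suffix)] + repl
            stems.add(base)
            # undo consonant doubling: "stopped" -> "stopp" -> "stop"
            if len(base) >= 3 and base[-1] == base[-2] and base[-1] not in "aeiou":
                stems.add(base[:-1])
            # restore silent e: "noted" -> "not" -> "note"
            if suffix in ("ing", "ed", "d"):
                stems.add(base + "e")
    return frozenset(stems)


def token_matches_lexicon(token: str, lexicon: TermLexicon) -> bool:
    """True iff the token's stem set intersects the lexicon (single-word terms)."""
    terms = set(lexicon.terms)
    return bool(stems_of(token) & terms)


def find_action_mentions(text: str, action_lexicon: TermLexicon | None = None) -> list[TermMention]:
    """Stem-aware occurrences of action terms, offsets into the original text."""
    lex = action_lexicon or load_lexicon("action")
    out = []
    for m in _TOKEN_RE.finditer(text):
        if token_matches_lexicon(m.group(0), lex):
            out.append(TermMention(lex.name, m.group(0).lower(), m.start(), m.end()))
    return out


def has_action_in_vicinity(
    text: str,
    mention: TermMention,
    window: int = 30,
    action_lexicon: TermLexicon | None = None,
) -> bool:
    """True iff an action term sits within ``window`` characters of a mention.

    The rule that enriched candidate notes: an action-lexicon mention must
    start within ``window`` characters before ``mention.start`` or end within
    ``window`` characters after ``mention.end``, measured on the original
    text. Monotone in ``window``.
    """
    if not (0 <= mention.start < mention.end <= len(text)):
        raise IndexError(
            f"mention [{mention.start}, {mention.end}) out of bounds for text of "
            f"length {len(text)}"
        )
    for am in find_action_mentions(text, action_lexicon):
        if am.start <= mention.start and mention.start - am.start <= window:
            return True
        if am.end >= mention.end and am.end - mention.end <= window:
            return True
        if am.start >= mention.start and am.end <= mention.end:
            return True  # action nested inside the mention span
    return False
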