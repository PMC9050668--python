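"""Keyword screening of free-text clinical fields for candidate death cases.

Deceased animals are rarely flagged in a structured field of primary-care
veterinary records; the working approach in the field is to search the
free-text clinical note and treatment fields with a small grammar of terms:

* bare token — matches a whole word, case-insensitively (``euth``);
* prefix — trailing ``*`` matches any word with that prefix (``pts*``
  matches ``pts`` and ``ptsd``);
* phrase — quoted words match consecutively (``"put to sleep"``);
* proximity — ``"home bury" ~ 1`` matches the phrase words in any order with
  at most one intervening token;
* conjunction — ``["bury" and "home"]`` requires all listed terms anywhere
  in the field.

The default configuration is the 15-term clinical-note list and 6-term
treatment list used in UK primary-care mortality screening.  Whether such
search engines match bare terms as whole tokens or substrings varies;
whole-token is the default here, with ``substring=True`` available on the
matcher for engines of the other persuasion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ConfigurationError, DataError
from .records import DeathRecord

__all__ = [
    "SearchTerm",
    "ScreenResult",
    "DEFAULT_NOTE_TERMS",
    "DEFAULT_TREATMENT_TERMS",
    "tokenize",
    "parse_term",
    "compile_terms",
    "Matcher",
    "screen",
    "screening_precision",
]

#: default clinical-note search terms
DEFAULT_NOTE_TERMS = (
    "euth",
    "pts*",
    "crem*",
    "ashes",
    "pento*",
    "casket",
    "beech",
    "decease*",
    "death",
    '"put to sleep"',
    "doa",
    "died",
    "killed",
    '"home bury" ~ 1',
    '["bury" and "home"]',
)

#: default treatment-field search terms
DEFAULT_TREATMENT_TERMS = (
    "euth*",
    "pento*",
    "crem*",
    "casket",
    "scatter",
    "beech",
)

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Case-fold and split on punctuation/whitespace. Empty text -> []."""
    return _TOKEN_RE.findall(text.lower())


@dataclass(frozen=True)
class SearchTerm:
    raw: str
    kind: str  # token | prefix | phrase | proximity | conjunction
    words: tuple[str, ...] = ()
    k: int = 0
    subterms: tuple["SearchTerm", ...] = ()


_QUOTED_RE = re.compile(r'^"([^"]+)"\s*(?:~\s*(\d+))?$')


def parse_term(raw: str) -> SearchTerm:
    """Parse one search-term expression into a :class:`SearchTerm`."""
    s = raw.strip()
    if not s:
        raise ConfigurationError("empty search term")

    if s.startswith("[") and s.endswith("]"):
        inner = s[1:-1]
        parts = re.split(r"\s+and\s+", inner, flags=re.IGNORECASE)
        if len(parts) < 2:
            raise ConfigurationError(f"conjunction needs >= 2 terms: {raw!r}")
        subs = tuple(parse_term(p) for p in parts)
        if any(t.kind == "conjunction" for t in subs):
            raise ConfigurationError(f"nested conjunction not supported: {raw!r}")
        return SearchTerm(raw=raw, kind="conjunction", subterms=subs)

    m = _QUOTED_RE.match(s)
    if m:
        words = tuple(tokenize(m.group(1)))
        if not words:
            raise ConfigurationError(f"empty phrase: {raw!r}")
        if m.group(2) is not None:
            return SearchTerm(raw=raw, kind="proximity", words=words, k=int(m.group(2)))
        if len(words) == 1:
            return SearchTerm(raw=raw, kind="token", words=words)
        return SearchTerm(raw=raw, kind="phrase", words=words)
    if "~" in s:
        raise ConfigurationError(f"proximity '~' requires a quoted phrase: {raw!r}")
    if '"' in s:
        raise ConfigurationError(f"unbalanced quotes in term: {raw!r}")

    if s.endswith("*"):
        stem = s[:-1]
        if not stem or "*" in stem:
            raise ConfigurationError(f"prefix term needs exactly one trailing '*': {raw!r}")
        return SearchTerm(raw=raw, kind="prefix", words=(stem.lower(),))
    if "*" in s:
        raise ConfigurationError(f"wildcard only allowed at the end of a term: {raw!r}")
    if re.search(r"\s", s):
        raise ConfigurationError(f"multi-word terms must be quoted: {raw!r}")
    return SearchTerm(raw=raw, kind="token", words=(s.lower(),))


def _match_term(term: SearchTerm, tokens: Sequence[str], substring: bool) -> list[int]:
    """Token offsets at which ``term`` matches (first token of the match)."""
    if term.kind == "token":
        w = term.words[0]
        if substring:
            return [i for i, t in enumerate(tokens) if w in t]
        return [i for i, t in enumerate(tokens) if t == w]
    if term.kind == "prefix":
        w = term.words[0]
        return [i for i, t in enumerate(tokens) if t.startswith(w)]
    if term.kind == "phrase":
        w = term.words
        L = len(w)
        return [
            i for i in range(len(tokens) - L + 1) if tuple(tokens[i : i + L]) == w
        ]
    if term.kind == "proximity":
        # unordered: all phrase words inside a window of len(words)+k tokens
        w = list(term.words)
        span = len(w) + term.k
        hits = []
        for i in range(len(tokens)):
            if tokens[i] not in w:  # anchor windows on a phrase word
                continue
            pool = list(tokens[i : i + span])
            if all(_take(pool, word) for word in w):
                hits.append(i)
        return hits
    if term.kind == "conjunction":
        offsets = []
        for sub in term.subterms:
            sub_hits = _match_term(sub, tokens, substring)
            if not sub_hits:
                return []
            offsets.append(min(sub_hits))
        return [min(offsets)]
    raise ConfigurationError(f"unknown term kind {term.kind!r}")


def _take(pool: list[str], word: str) -> bool:
    try:
        pool.remove(word)
        return True
    except ValueError:
        return False


@dataclass
class Matcher:
    """Compiled screening matcher: note terms against the clinical note,
    treatment terms against the treatment field."""

    note_terms: tuple[SearchTerm, ...]
    treatment_terms: tuple[SearchTerm, ...]
    substring: bool = False

    def match_field(self, text: str, which: str) -> list[tuple[str, str, int]]:
        tokens = tokenize(text)
        terms = self.note_terms if which == "clinical_note" else self.treatment_terms
        hits = []
        for term in terms:
            for off in _match_term(term, tokens, self.substring):
                hits.append((which, term.raw, off))
        return hits


@dataclass
class ScreenResult:
    animal_id: str
    matched: bool
    hits: list[tuple[str, str, int]] = field(default_factory=list)


def compile_terms(
    note_terms: Optional[Iterable[str]] = None,
    treatment_terms: Optional[Iterable[str]] = None,
    substring: bool = False,
) -> Matcher:
    """Compile raw term expressions into a :class:`Matcher`.

    Omitted lists fall back to the default configuration.
    """
    nt = DEFAULT_NOTE_TERMS if note_terms is None else tuple(note_terms)
    tt = DEFAULT_TREATMENT_TERMS if treatment_terms is None else tuple(treatment_terms)
    return Matcher(
        note_terms=tuple(parse_term(t) for t in nt),
        treatment_terms=tuple(parse_term(t) for t in tt),
        substring=substring,
    )


def screen(records: Iterable[DeathRecord], matcher: Matcher) -> list[ScreenResult]:
    """One :class:`ScreenResult` per record, hit offsets reported for audit."""
    out = []
    for rec in records:
        hits = matcher.match_field(rec.clinical_note, "clinical_note")
        hits += matcher.match_field(rec.treatment_text, "treatment_text")
        out.append(ScreenResult(animal_id=rec.animal_id, matched=bool(hits), hits=hits))
    return out


def screening_precision(
    results: Iterable[ScreenResult], labels: Mapping[str, bool]
) -> tuple[float, int, int]:
    """Confirmed-among-matched proportion of the screen.

    Returns ``(proportion, confirmed, matched)``.  Every matched id must be
    labelled (manual review in the source workflow).
    """
    matched_ids = [r.animal_id for r in results if r.matched]
    missing = [i for i in matched_ids if i not in labels]
    if missing:
        raise DataError(f"matched ids without a confirmation label: {missing[:10]}")
    confirmed = sum(1 for i in matched_ids if labels[i])
    denom = len(matched_ids)
    return (confirmed / denom if denom else float("nan"), confirmed, denom)
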