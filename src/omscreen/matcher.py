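"""Scan visit free text for search terms and apply the exclusion-combination rule.

The matching semantics, in order:

1. *Occurrence finding* — every boundary-respecting occurrence of every
   search term is located.  An occurrence at ``[i, j)`` qualifies only if the
   characters at ``i-1`` and ``j`` (when they exist) are not alphanumeric, so
   a short abbreviation like ``'tm'`` never fires inside ``"treatment"``.
   ``'/'`` inside a term (``'T/M'``) is matched literally.  Matching operates
   on the raw string; no normalization is applied.

2. *Exclusion combination* — each occurrence is compared against every
   exclusion-word occurrence in the text.  If one falls within the
   :class:`~omscreen.lexicon.CombinationPolicy` scope of the match, the match
   is marked excluded and the nearest qualifying occurrence (by character
   distance, ties to the earlier offset) is recorded as ``excluded_by``.
   Exclusion is per match: a negated tympanic-membrane finding does not
   suppress an independent diagnosis term elsewhere in the note.

3. *Visit classification* — a visit is flagged ("OM considered") if and only
   if at least one match survives exclusion.

Tokens, for window/phrase scopes, are maximal runs of alphanumeric
characters plus internal ``'/'``; sentence boundaries are ``.``, ``!``,
``?`` and newline.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .lexicon import CombinationPolicy, ExclusionWord, Lexicon, SearchTerm

__all__ = [
    "VisitRecord",
    "ExclusionHit",
    "TermMatch",
    "ScreenResult",
    "MatchIntegrityError",
    "DuplicateVisitIdError",
    "find_term_occurrences",
    "apply_exclusion_rules",
    "screen_visit",
    "screen_corpus",
    "token_spans",
    "occurrence_in_scope",
]

audit_log = logging.getLogger("omscreen.audit")

# Token: maximal run of alphanumerics, optionally joined by internal '/'
# (so 'T/M' is one token).  Underscore is punctuation here, unlike \w.
_TOKEN_RE = re.compile(r"[^\W_]+(?:/[^\W_]+)*", re.UNICODE)
_SENTENCE_BREAKS = frozenset(".!?\n")


class MatchIntegrityError(ValueError):
    """A match span does not reproduce its term surface from the text."""


class DuplicateVisitIdError(ValueError):
    """Two records in one corpus share a visit_id."""


@dataclass(frozen=True)
class VisitRecord:
    """One free-text primary care consultation note."""

    child_id: str
    visit_id: str
    text: str
    visit_date: Optional[str] = None  # ISO-8601 date or None


@dataclass(frozen=True)
class ExclusionHit:
    """An exclusion-word occurrence responsible for excluding a match."""

    word: ExclusionWord
    start: int
    end: int


@dataclass(frozen=True)
class TermMatch:
    """One search-term occurrence, with its exclusion status."""

    term: SearchTerm
    start: int  # 0-based, inclusive
    end: int  # exclusive
    excluded: bool = False
    excluded_by: Optional[ExclusionHit] = None

    def __post_init__(self) -> None:
        if (self.excluded_by is not None) != self.excluded:
            raise ValueError("excluded_by must be present iff excluded is true")


@dataclass(frozen=True)
class ScreenResult:
    """Per-visit algorithm output with full match provenance."""

    visit_id: str
    flagged: bool
    matches: tuple[TermMatch, ...] = field(default=())


def _surfaces_equal(text_slice: str, surface: str, case_sensitive: bool) -> bool:
    if case_sensitive:
        return text_slice == surface
    return text_slice.lower() == surface.lower()


def _scan_surface(text: str, surface: str, case_sensitive: bool) -> Iterable[tuple[int, int]]:
    """Yield boundary-respecting occurrence spans of one surface string."""
    hay = text if case_sensitive else text.lower()
    needle = surface if case_sensitive else surface.lower()
    n = len(text)
    k = len(needle)
    i = hay.find(needle)
    while i != -1:
        j = i + k
        left_ok = i == 0 or not text[i - 1].isalnum()
        right_ok = j == n or not text[j].isalnum()
        if left_ok and right_ok:
            yield i, j
        i = hay.find(needle, i + 1)  # step 1: allow overlapping occurrences


def find_term_occurrences(text: str, lexicon: Lexicon) -> list[TermMatch]:
    """Every boundary-respecting occurrence of every search term.

    Returns matches sorted by ``(start, end)`` with ``excluded=False``.
    Overlapping occurrences of different terms are all reported; occurrences
    with an identical ``(surface, start, end)`` (possible when the same
    surface is listed under both case rules) are collapsed to the first term
    in lexicon order.
    """
    out: list[tuple[int, int, int, SearchTerm]] = []
    seen: set[tuple[str, int, int]] = set()
    for idx, term in enumerate(lexicon.search_terms):
        for i, j in _scan_surface(text, term.surface, term.case_sensitive):
            key = (term.surface, i, j)
            if key in seen:
                continue
            seen.add(key)
            out.append((i, j, idx, term))
    out.sort(key=lambda t: (t[0], t[1], t[2]))
    return [TermMatch(term=term, start=i, end=j) for i, j, _, term in out]


def token_spans(text: str) -> list[tuple[int, int]]:
    """Character spans of the tokens of ``text``, left to right."""
    return [(m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def _covering_token_range(
    spans: Sequence[tuple[int, int]], start: int, end: int
) -> Optional[tuple[int, int]]:
    """Indices (first, last) of tokens overlapping [start, end), or None."""
    first = last = None
    for idx, (s, e) in enumerate(spans):
        if s < end and e > start:
            if first is None:
                first = idx
            last = idx
        elif first is not None:
            break
    if first is None:
        return None
    return first, last


def _sentence_index(text: str, offset: int) -> int:
    return sum(1 for ch in text[:offset] if ch in _SENTENCE_BREAKS)


def occurrence_in_scope(
    text: str,
    match_span: tuple[int, int],
    occ_span: tuple[int, int],
    policy: CombinationPolicy,
    spans: Optional[Sequence[tuple[int, int]]] = None,
) -> bool:
    """Does an occurrence at ``occ_span`` fall within the policy scope of a
    match at ``match_span``?

    Occurrences overlapping the match span itself never qualify (the same
    characters are not a *combination*).  For ``phrase``/``window``, distance
    is measured in tokens between the token ranges covering each span;
    ``phrase`` behaves as a one-token window.  ``bidirectional=False``
    restricts those two modes to occurrences after the match.
    """
    ms, me = match_span
    os_, oe = occ_span
    if os_ < me and oe > ms:  # overlap with the match itself
        return False
    mode = policy.mode
    if mode == "record":
        return True
    if mode == "sentence":
        return _sentence_index(text, ms) == _sentence_index(text, os_)
    # phrase / window: token-distance scope
    if spans is None:
        spans = token_spans(text)
    mrange = _covering_token_range(spans, ms, me)
    orange = _covering_token_range(spans, os_, oe)
    if mrange is None or orange is None:
        return False
    limit = 1 if mode == "phrase" else policy.window_tokens
    if orange[0] > mrange[1]:  # occurrence after the match
        return orange[0] - mrange[1] <= limit
    if orange[1] < mrange[0]:  # occurrence before the match
        return policy.bidirectional and (mrange[0] - orange[1]) <= limit
    return True  # token ranges overlap (e.g. 'tm/normal' is one token)


def apply_exclusion_rules(
    text: str, matches: Sequence[TermMatch], lexicon: Lexicon
) -> list[TermMatch]:
    """Set the ``excluded`` flag on each match per the combination policy.

    Each match is compared against every exclusion-word occurrence in the
    text; a match is excluded when at least one occurrence is in scope, and
    ``excluded_by`` records the nearest qualifying occurrence by character
    distance (ties broken by the earlier offset).  Raises
    :class:`MatchIntegrityError` if a match span does not reproduce its term
    surface from ``text``.
    """
    for m in matches:
        if not (0 <= m.start < m.end <= len(text)) or not _surfaces_equal(
            text[m.start : m.end], m.term.surface, m.term.case_sensitive
        ):
            raise MatchIntegrityError(
                f"match span {m.start}..{m.end} does not reproduce "
                f"term {m.term.surface!r} in text"
            )
    occurrences: list[ExclusionHit] = []
    for word in lexicon.exclusion_words:
        for i, j in _scan_surface(text, word.surface, word.case_sensitive):
            occurrences.append(ExclusionHit(word=word, start=i, end=j))
    if not occurrences:
        return list(matches)
    spans = token_spans(text)
    out: list[TermMatch] = []
    for m in matches:
        best: Optional[ExclusionHit] = None
        best_key: Optional[tuple[int, int]] = None
        for occ in occurrences:
            if not occurrence_in_scope(
                text, (m.start, m.end), (occ.start, occ.end), lexicon.policy, spans
            ):
                continue
            if occ.start >= m.end:
                dist = occ.start - m.end
            elif occ.end <= m.start:
                dist = m.start - occ.end
            else:
                dist = 0
            key = (dist, occ.start)
            if best_key is None or key < best_key:
                best, best_key = occ, key
        if best is None:
            out.append(m)
        else:
            out.append(replace(m, excluded=True, excluded_by=best))
    return out


def screen_visit(record: VisitRecord, lexicon: Lexicon) -> ScreenResult:
    """Classify one visit: flagged iff any match survives exclusion."""
    matches = apply_exclusion_rules(
        record.text, find_term_occurrences(record.text, lexicon), lexicon
    )
    flagged = any(not m.excluded for m in matches)
    return ScreenResult(visit_id=record.visit_id, flagged=flagged, matches=tuple(matches))


def screen_corpus(records: Sequence[VisitRecord], lexicon: Lexicon) -> list[ScreenResult]:
    """Screen every record, preserving input order.

    Visit ids must be unique; duplicates abort before any screening.  One
    audit-log line is emitted per excluded match (logger ``omscreen.audit``).
    """
    seen: set[str] = set()
    dupes: list[str] = []
    for r in records:
        if r.visit_id in seen:
            dupes.append(r.visit_id)
        seen.add(r.visit_id)
    if dupes:
        raise DuplicateVisitIdError(f"duplicate visit_id(s): {sorted(set(dupes))}")
    results = []
    for record in records:
        result = screen_visit(record, lexicon)
        for m in result.matches:
            if m.excluded and m.excluded_by is not None:
                audit_log.info(
                    "visit=%s term=%r span=%d..%d excluded_by=%r span=%d..%d",
                    record.visit_id,
                    m.term.surface,
                    m.start,
                    m.end,
                    m.excluded_by.word.surface,
                    m.excluded_by.start,
                    m.excluded_by.end,
                )
        results.append(result)
    return results
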