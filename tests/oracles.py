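"""Independent brute-force oracles used to check the implementation.

These are deliberately written from the stated semantics, not from the
implementation: exhaustive substring enumeration for occurrence finding,
character-walk tokenization, exhaustive (match, exclusion-occurrence) scope
checks, and binomial-tail bisection for the exact interval.
"""

from __future__ import annotations

from scipy import stats as _stats


def oracle_occurrences(text: str, surface: str, case_sensitive: bool) -> list[tuple[int, int]]:
    """Every boundary-respecting occurrence, by exhaustive position scan."""
    out = []
    k = len(surface)
    for i in range(len(text) - k + 1):
        seg = text[i : i + k]
        if case_sensitive:
            if seg != surface:
                continue
        elif seg.lower() != surface.lower():
            continue
        j = i + k
        if i > 0 and text[i - 1].isalnum():
            continue
        if j < len(text) and text[j].isalnum():
            continue
        out.append((i, j))
    return out


def oracle_find(text: str, lexicon) -> list[tuple[int, int, str]]:
    """All term occurrences as (start, end, surface), sorted, deduplicated."""
    found = []
    seen = set()
    for term in lexicon.search_terms:
        for i, j in oracle_occurrences(text, term.surface, term.case_sensitive):
            key = (term.surface, i, j)
            if key not in seen:
                seen.add(key)
                found.append((i, j, term.surface))
    return sorted(found)


def oracle_tokens(text: str) -> list[tuple[int, int]]:
    """Maximal alphanumeric runs joined by internal '/', by character walk."""
    spans = []
    i, n = 0, len(text)
    while i < n:
        if not text[i].isalnum():
            i += 1
            continue
        j = i
        while j < n and text[j].isalnum():
            j += 1
        while j < n and text[j] == "/" and j + 1 < n and text[j + 1].isalnum():
            j += 1
            while j < n and text[j].isalnum():
                j += 1
        spans.append((i, j))
        i = j
    return spans


def _covering(spans: list[tuple[int, int]], start: int, end: int) -> tuple[int, int] | None:
    idx = [t for t, (s, e) in enumerate(spans) if s < end and e > start]
    if not idx:
        return None
    return idx[0], idx[-1]


def oracle_in_scope(text: str, mspan: tuple[int, int], ospan: tuple[int, int], policy) -> bool:
    ms, me = mspan
    os_, oe = ospan
    if os_ < me and oe > ms:
        return False
    if policy.mode == "record":
        return True
    if policy.mode == "sentence":
        breaks = ".!?\n"
        sid = lambda off: sum(1 for ch in text[:off] if ch in breaks)  # noqa: E731
        return sid(ms) == sid(os_)
    spans = oracle_tokens(text)
    mr = _covering(spans, ms, me)
    orr = _covering(spans, os_, oe)
    if mr is None or orr is None:
        return False
    limit = 1 if policy.mode == "phrase" else policy.window_tokens
    if orr[0] > mr[1]:
        return orr[0] - mr[1] <= limit
    if orr[1] < mr[0]:
        return policy.bidirectional and mr[0] - orr[1] <= limit
    return True


def oracle_screen(text: str, lexicon) -> tuple[bool, set[tuple[int, int, str]]]:
    """(flagged, retained-match set) by exhaustive enumeration."""
    excl_occ = []
    for word in lexicon.exclusion_words:
        excl_occ.extend(oracle_occurrences(text, word.surface, word.case_sensitive))
    retained = set()
    for i, j, surface in oracle_find(text, lexicon):
        excluded = any(
            oracle_in_scope(text, (i, j), occ, lexicon.policy) for occ in excl_occ
        )
        if not excluded:
            retained.add((i, j, surface))
    return bool(retained), retained


def oracle_clopper_pearson(k: int, n: int, level: float = 0.95, tol: float = 1e-12):
    """Exact interval by bisection on the binomial tail probabilities."""
    alpha = 1.0 - level

    def bisect(f, target, increasing):
        lo, hi = 0.0, 1.0
        while hi - lo > tol:
            mid = (lo + hi) / 2.0
            value = f(mid)
            if (value < target) == increasing:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2.0

    if k == 0:
        lower = 0.0
    else:
        # P(X >= k | p) increases in p; lower bound solves it = alpha/2
        lower = bisect(lambda p: _stats.binom.sf(k - 1, n, p), alpha / 2.0, True)
    if k == n:
        upper = 1.0
    else:
        # P(X <= k | p) decreases in p; upper bound solves it = alpha/2
        upper = bisect(lambda p: _stats.binom.cdf(k, n, p), alpha / 2.0, False)
    return lower, upper
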