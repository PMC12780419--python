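import numpy as np
import pytest

from omscreen.lexicon import (
    CombinationPolicy,
    ExclusionWord,
    Lexicon,
    SearchTerm,
    seed_lexicon,
)
from omscreen.matcher import VisitRecord


@pytest.fixture(scope="session")
def seed_lex():
    return seed_lexicon()


@pytest.fixture
def small_lexicon():
    """Compact lexicon covering the documented hard cases."""
    return Lexicon(
        search_terms=(
            SearchTerm(surface="otitis media", case_sensitive=False),
            SearchTerm(surface="OM", case_sensitive=True),
            SearchTerm(surface="AOM", case_sensitive=True),
            SearchTerm(surface="ROM", case_sensitive=True),
            SearchTerm(surface="T/M", case_sensitive=True),
            SearchTerm(surface="tm", case_sensitive=True),
            SearchTerm(surface="TM", case_sensitive=True),
        ),
        exclusion_words=(ExclusionWord(surface="normal", case_sensitive=False),),
        policy=CombinationPolicy(mode="window", window_tokens=3, bidirectional=True),
        version="test-1",
    )


@pytest.fixture
def tiny_corpus():
    return [
        VisitRecord("c1", "v1", "seen with fever, dx otitis media, amoxicillin started", "2010-02-01"),
        VisitRecord("c1", "v2", "TM normal both sides, viral illness", "2010-03-05"),
        VisitRecord("c2", "v3", "routine immunisation visit, no concerns", "2010-02-11"),
        VisitRecord("c2", "v4", "knee ROM full and pain free after fall", "2010-04-02"),
        VisitRecord("c3", "v5", "", "2010-05-01"),
    ]


# Vocabulary for randomized matcher-vs-oracle testing: terms, exclusion
# words, decoys sharing prefixes, and boundary punctuation.
MATCH_VOCAB = [
    "tm", "TM", "T/M", "t/m", "OM", "om", "AOM", "ROM", "rom",
    "otitis media", "otitis", "media",
    "normal", "Normal", "NORMAL", "normally", "normals",
    "treatment", "tms", "atm", "roman", "aroma", "brother",
    "ear", "L", "R", "red", "looks",
]
SEPARATORS = [" ", " ", " ", ". ", ", ", "\n", "! ", "? ", "/", "-", ""]


def random_text(rng: np.random.Generator, max_tokens: int = 12) -> str:
    n = int(rng.integers(0, max_tokens))
    parts = []
    for _ in range(n):
        parts.append(MATCH_VOCAB[rng.integers(0, len(MATCH_VOCAB))])
        parts.append(SEPARATORS[rng.integers(0, len(SEPARATORS))])
    return "".join(parts)[:500]
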