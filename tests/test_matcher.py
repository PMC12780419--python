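import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omscreen.lexicon import CombinationPolicy, ExclusionWord, Lexicon, SearchTerm
from omscreen.matcher import (
    DuplicateVisitIdError,
    MatchIntegrityError,
    TermMatch,
    VisitRecord,
    apply_exclusion_rules,
    find_term_occurrences,
    screen_corpus,
    screen_visit,
    token_spans,
)

from .conftest import MATCH_VOCAB, SEPARATORS, random_text
from .oracles import oracle_find, oracle_screen, oracle_tokens


class TestFindTermOccurrences:
    def test_phrase_in_context(self, small_lexicon):
        matches = find_term_occurrences("brother has otitis media", small_lexicon)
        assert [(m.start, m.end, m.term.surface) for m in matches] == [
            (12, 24, "otitis media")
        ]

    def test_empty_text(self, small_lexicon):
        assert find_term_occurrences("", small_lexicon) == []

    def test_boundary_rule_blocks_internal_substring(self, small_lexicon):
        # 'tm' inside "treatment" fails the boundary predicate
        assert find_term_occurrences("treatment given", small_lexicon) == []
        assert oracle_find("treatment given", small_lexicon) == []

    def test_case_sensitivity_respected(self, small_lexicon):
        assert find_term_occurrences("om at home", small_lexicon) == []
        matches = find_term_occurrences("OM at home", small_lexicon)
        assert [m.term.surface for m in matches] == ["OM"]

    def test_case_insensitive_term(self, small_lexicon):
        matches = find_term_occurrences("Otitis Media suspected", small_lexicon)
        assert [(m.start, m.end) for m in matches] == [(0, 12)]

    def test_slash_term_is_literal(self, small_lexicon):
        matches = find_term_occurrences("T/M red", small_lexicon)
        assert [m.term.surface for m in matches] == ["T/M"]

    def test_overlapping_terms_all_reported(self, small_lexicon):
        # 'otitis media' (ci) and nothing else overlaps here, so craft one:
        lex = Lexicon(
            search_terms=(
                SearchTerm(surface="otitis media", case_sensitive=False),
                SearchTerm(surface="media", case_sensitive=False),
            )
        )
        matches = find_term_occurrences("otitis media", lex)
        assert {(m.start, m.end) for m in matches} == {(0, 12), (7, 12)}

    def test_sorted_by_start_then_end(self, small_lexicon, seed_lex):
        rng = np.random.default_rng(7)
        for _ in range(50):
            text = random_text(rng)
            matches = find_term_occurrences(text, seed_lex)
            keys = [(m.start, m.end) for m in matches]
            assert keys == sorted(keys)

    def test_all_excluded_false(self, small_lexicon):
        for m in find_term_occurrences("TM normal OM", small_lexicon):
            assert m.excluded is False and m.excluded_by is None

    def test_matches_oracle_on_random_texts(self, seed_lex):
        rng = np.random.default_rng(11)
        for _ in range(300):
            text = random_text(rng)
            got = [(m.start, m.end, m.term.surface) for m in find_term_occurrences(text, seed_lex)]
            assert sorted(got) == oracle_find(text, seed_lex)


class TestTokenization:
    @pytest.mark.parametrize(
        "text",
        ["T/M red", "a/b/c d", "tm/normal", "x _y z", "", "...", "a.b!c\nd", "50mg b.d."],
    )
    def test_token_spans_match_oracle(self, text):
        assert token_spans(text) == oracle_tokens(text)


class TestApplyExclusionRules:
    def test_tm_normal_excluded(self, small_lexicon):
        text = "tm normal"
        matches = find_term_occurrences(text, small_lexicon)
        out = apply_exclusion_rules(text, matches, small_lexicon)
        assert len(out) == 1
        assert out[0].excluded is True
        assert out[0].excluded_by.word.surface == "normal"

    def test_no_exclusion_words_is_noop(self):
        lex = Lexicon(search_terms=(SearchTerm(surface="OM"),))
        text = "OM noted"
        matches = find_term_occurrences(text, lex)
        assert apply_exclusion_rules(text, matches, lex) == matches

    def test_per_match_exclusion(self, small_lexicon):
        text = "TM normal but L ear AOM"
        out = apply_exclusion_rules(
            text, find_term_occurrences(text, small_lexicon), small_lexicon
        )
        by_surface = {m.term.surface: m for m in out}
        assert by_surface["TM"].excluded is True
        assert by_surface["AOM"].excluded is False
        assert any(not m.excluded for m in out)  # visit still flagged

    def test_span_mismatch_raises_integrity_error(self, small_lexicon):
        bogus = TermMatch(term=SearchTerm(surface="OM"), start=0, end=2)
        with pytest.raises(MatchIntegrityError):
            apply_exclusion_rules("ear ache", [bogus], small_lexicon)

    def test_excluded_by_is_nearest_occurrence(self, small_lexicon):
        text = "normal ear TM normal"
        out = apply_exclusion_rules(
            text, find_term_occurrences(text, small_lexicon), small_lexicon
        )
        (m,) = out
        assert m.excluded_by.start == 14  # the occurrence after, 1 char away

    def test_tie_broken_by_earlier_offset(self):
        lex = Lexicon(
            search_terms=(SearchTerm(surface="TM"),),
            exclusion_words=(ExclusionWord(surface="ok", case_sensitive=False),),
            policy=CombinationPolicy(mode="window", window_tokens=2, bidirectional=True),
        )
        text = "ok TM ok"
        out = apply_exclusion_rules(text, find_term_occurrences(text, lex), lex)
        (m,) = out
        assert m.excluded_by.start == 0  # equal distance; earlier offset wins

    def test_bidirectional_false_ignores_preceding_word(self, small_lexicon):
        lex = small_lexicon.model_copy(
            update={
                "policy": CombinationPolicy(mode="window", window_tokens=3, bidirectional=False)
            }
        )
        text = "normal TM"
        out = apply_exclusion_rules(text, find_term_occurrences(text, lex), lex)
        assert out[0].excluded is False
        text2 = "TM normal"
        out2 = apply_exclusion_rules(text2, find_term_occurrences(text2, lex), lex)
        assert out2[0].excluded is True

    @pytest.mark.parametrize(
        "mode,text,expect_excluded",
        [
            ("phrase", "TM normal", True),
            ("phrase", "TM looks normal", False),  # two tokens away
            ("window", "TM looks normal", True),  # within 3 tokens
            ("window", "TM a b c normal", False),  # four tokens away
            ("sentence", "TM red today. all normal now", False),
            ("sentence", "TM red, all normal now", True),
            ("record", "TM red today. all normal now", True),
        ],
    )
    def test_policy_modes(self, small_lexicon, mode, text, expect_excluded):
        lex = small_lexicon.model_copy(
            update={"policy": CombinationPolicy(mode=mode, window_tokens=3, bidirectional=True)}
        )
        out = apply_exclusion_rules(text, find_term_occurrences(text, lex), lex)
        tm = [m for m in out if m.term.surface == "TM"]
        assert tm and tm[0].excluded is expect_excluded


class TestScreenVisit:
    def test_family_mention_is_flagged_by_design(self, small_lexicon):
        r = screen_visit(VisitRecord("c", "v", "brother has otitis media"), small_lexicon)
        assert r.flagged is True

    def test_empty_text_not_flagged(self, small_lexicon):
        r = screen_visit(VisitRecord("c", "v", ""), small_lexicon)
        assert r.flagged is False and r.matches == ()

    def test_ambiguous_rom_is_flagged(self, small_lexicon):
        # documents the 'range of movement' false-positive mode
        r = screen_visit(VisitRecord("c", "v", "ROM improving since physio"), small_lexicon)
        assert r.flagged is True
        assert [m.term.surface for m in r.matches] == ["ROM"]

    def test_flagged_iff_some_match_retained(self, seed_lex):
        rng = np.random.default_rng(23)
        for _ in range(100):
            r = screen_visit(VisitRecord("c", "v", random_text(rng)), seed_lex)
            assert r.flagged == any(not m.excluded for m in r.matches)

    def test_deterministic(self, seed_lex):
        rec = VisitRecord("c", "v", "TM normal but AOM on L. brother has otitis media")
        assert screen_visit(rec, seed_lex) == screen_visit(rec, seed_lex)


class TestScreenCorpus:
    def test_count(self, small_lexicon):
        records = [
            VisitRecord("c1", "v1", "otitis media today"),
            VisitRecord("c1", "v2", "no ear findings"),
            VisitRecord("c2", "v3", "well child check"),
        ]
        results = screen_corpus(records, small_lexicon)
        assert sum(r.flagged for r in results) == 1
        assert [r.visit_id for r in results] == ["v1", "v2", "v3"]

    def test_duplicate_visit_id_rejected(self, small_lexicon):
        records = [VisitRecord("c1", "v1", "a"), VisitRecord("c2", "v1", "b")]
        with pytest.raises(DuplicateVisitIdError, match="v1"):
            screen_corpus(records, small_lexicon)

    def test_determinism(self, seed_lex, tiny_corpus):
        assert screen_corpus(tiny_corpus, seed_lex) == screen_corpus(tiny_corpus, seed_lex)

    def test_audit_line_per_excluded_match(self, small_lexicon, caplog):
        records = [VisitRecord("c1", "v1", "TM normal"), VisitRecord("c1", "v2", "AOM")]
        with caplog.at_level("INFO", logger="omscreen.audit"):
            screen_corpus(records, small_lexicon)
        audit = [r for r in caplog.records if r.name == "omscreen.audit"]
        assert len(audit) == 1 and "v1" in audit[0].getMessage()

    def test_flagged_set_matches_oracle_on_random_corpus(self, seed_lex):
        rng = np.random.default_rng(31)
        records = [VisitRecord("c", f"v{i}", random_text(rng)) for i in range(50)]
        results = screen_corpus(records, seed_lex)
        for rec, res in zip(records, results):
            flagged, _ = oracle_screen(rec.text, seed_lex)
            assert res.flagged == flagged


# ---------------------------------------------------------------------------
# Property tests
# ---------------------------------------------------------------------------

_texts = st.lists(
    st.tuples(st.sampled_from(MATCH_VOCAB), st.sampled_from(SEPARATORS)),
    max_size=14,
).map(lambda pairs: "".join(a + b for a, b in pairs)[:500])

_policies = st.builds(
    CombinationPolicy,
    mode=st.sampled_from(["phrase", "window", "sentence", "record"]),
    window_tokens=st.integers(1, 4),
    bidirectional=st.booleans(),
)


@settings(max_examples=200, deadline=None)
@given(text=_texts, policy=_policies)
def test_retained_set_equals_oracle_property(seed_lex, text, policy):
    lex = seed_lex.model_copy(update={"policy": policy})
    result = screen_visit(VisitRecord("c", "v", text), lex)
    got = {(m.start, m.end, m.term.surface) for m in result.matches if not m.excluded}
    flagged, want = oracle_screen(text, lex)
    assert got == want
    assert result.flagged == flagged


@settings(max_examples=100, deadline=None)
@given(text=_texts)
def test_adding_search_term_never_unflags(seed_lex, text):
    lex = Lexicon(
        search_terms=seed_lex.search_terms[:3],
        exclusion_words=seed_lex.exclusion_words,
        policy=seed_lex.policy,
    )
    bigger = Lexicon(
        search_terms=seed_lex.search_terms,
        exclusion_words=seed_lex.exclusion_words,
        policy=seed_lex.policy,
    )
    rec = VisitRecord("c", "v", text)
    if screen_visit(rec, lex).flagged:
        assert screen_visit(rec, bigger).flagged


@settings(max_examples=100, deadline=None)
@given(text=_texts)
def test_adding_exclusion_word_never_flags(seed_lex, text):
    fewer = seed_lex.model_copy(update={"exclusion_words": ()})
    rec = VisitRecord("c", "v", text)
    if not screen_visit(rec, fewer).flagged:
        assert not screen_visit(rec, seed_lex).flagged


@settings(max_examples=150, deadline=None)
@given(text=_texts)
def test_span_integrity(seed_lex, text):
    for m in screen_visit(VisitRecord("c", "v", text), seed_lex).matches:
        seg = text[m.start : m.end]
        if m.term.case_sensitive:
            assert seg == m.term.surface
        else:
            assert seg.lower() == m.term.surface.lower()
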