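"""Tokenizer, mention finder, and negation rule."""

import pytest
from hypothesis import given, settings, strategies as st

from spictminer import (
    Lexicon,
    NegationCue,
    TermEntry,
    annotate,
    assign_polarity,
    count_words,
    find_mentions,
    tokenize,
)


def entry(surface, ind=5, profiles=("strict", "relaxed"), **kw):
    return TermEntry(surface=surface, indicator_id=ind, profiles=frozenset(profiles), **kw)


class TestTokenize:
    def test_whitespace_split(self, lex):
        assert [t.text for t in tokenize("no pain", lex)] == ["no", "pain"]

    def test_punctuation_is_separate_tokens(self, lex):
        toks = tokenize("no pain today.", lex)
        assert [(t.text, t.kind) for t in toks] == [
            ("no", "word"), ("pain", "word"), ("today", "word"), (".", "punct")]

    def test_empty_text(self, lex):
        assert tokenize("", lex) == []
        assert count_words("", lex) == 0

    def test_greedy_longest_match(self):
        lx = Lexicon(segmentation_words=("ab", "abc", "d"))
        assert [t.text for t in tokenize("abcd", lx)] == ["abc", "d"]

    def test_unknown_fallback_single_chars(self):
        lx = Lexicon(segmentation_words=("ab",))
        assert [(t.text, t.kind) for t in tokenize("abxz", lx)] == [
            ("ab", "word"), ("x", "unknown"), ("z", "unknown")]

    def test_segmentation_word_count(self):
        lx = Lexicon(segmentation_words=("ab", "cd"))
        assert count_words("abcd", lx) == 2

    def test_latin_untouched_without_unsegmented_entries(self, lex):
        # default lexicon has only segmented surfaces: English never chopped
        assert [t.text for t in tokenize("underweight", lex)] == ["underweight"]

    def test_mixed_script_run_split_at_boundary(self):
        lx = Lexicon(segmentation_words=("αβγ", "δεζ"))
        toks = tokenize("pain αβγδεζ", lx)
        assert [t.text for t in toks] == ["pain", "αβγ", "δεζ"]

    @settings(max_examples=200, deadline=None)
    @given(st.text(alphabet="ab xz.;αβγδ,", max_size=60))
    def test_reconstruction_property(self, text):
        """Token spans are sorted, disjoint, and cover all non-whitespace."""
        lx = Lexicon(segmentation_words=("ab", "abc", "αβ", "γδ"))
        toks = tokenize(text, lx)
        pos = 0
        covered = []
        for t in toks:
            assert t.start >= pos
            assert text[t.start:t.end] == t.text
            covered.extend(range(t.start, t.end))
            pos = t.end
        expected = [i for i, ch in enumerate(text) if not ch.isspace()]
        assert covered == expected


class TestFindMentions:
    def test_strict_vs_relaxed_weight_loss(self, lex):
        assert [m.indicator_id for m in find_mentions(
            "significant weight loss noted", lex, "strict")] == [4]
        assert find_mentions("patient is underweight", lex, "strict") == []
        assert [m.indicator_id for m in find_mentions(
            "patient is underweight", lex, "relaxed")] == [4]

    def test_longest_match_wins_within_indicator(self, lex):
        ms = find_mentions("significant weight loss", lex, "relaxed")
        assert [m.entry.surface for m in ms] == ["significant weight loss"]

    def test_case_insensitive_literal_matching(self, lex):
        assert len(find_mentions("Significant Weight LOSS", lex, "strict")) == 1

    def test_repeated_term_yields_multiple_mentions(self, lex):
        ms = find_mentions("pain here. pain there.", lex, "relaxed")
        assert len(ms) == 2 and all(m.indicator_id == 5 for m in ms)

    def test_regex_entry_matches_raw_text(self):
        lx = Lexicon(entries=(entry(r"stage\s+iv", match_kind="regex"),))
        ms = find_mentions("known Stage  IV disease", lx, "strict")
        assert len(ms) == 1

    def test_strict_subset_of_relaxed_on_notes(self, lex):
        texts = [
            "pain and significant weight loss. asks for palliative care.",
            "no dyspnea but edema. underweight. persistent symptoms.",
            "refractory pain. comfort care discussed; bedridden.",
        ]
        for text in texts:
            strict = {(m.start, m.end, m.indicator_id)
                      for m in find_mentions(text, lex, "strict")}
            relaxed = {(m.start, m.end, m.indicator_id)
                       for m in find_mentions(text, lex, "relaxed")}
            assert strict <= relaxed

    def test_brute_force_oracle_on_token_boundaries(self, lex):
        """Literal matching equals a substring scan restricted to tokens."""
        import random

        rng = random.Random(7)
        filler = ["alpha", "bravo", "delta", "golf", "hotel", "kilo"]
        single_word_terms = {"pain": 5, "dyspnea": 5, "underweight": 4,
                            "bedridden": 1, "ascites": 5}
        for _ in range(50):
            words = [rng.choice(filler + list(single_word_terms)) for _ in range(30)]
            text = " ".join(words)
            expected = set()
            pos = 0
            for w in words:
                if w in single_word_terms:
                    expected.add((pos, pos + len(w), single_word_terms[w]))
                pos += len(w) + 1
            got = {(m.start, m.end, m.indicator_id)
                   for m in find_mentions(text, lex, "relaxed")}
            assert got == expected


class TestAssignPolarity:
    @pytest.mark.parametrize("text,polarity", [
        ("no pain", "negated"),
        ("pain", "affirmed"),
        ("denies pain", "negated"),
        ("without any pain", "negated"),
        ("no fever but pain persists", "affirmed"),   # "but" breaks the scope
        ("no improvement. pain persists", "affirmed"),  # "." breaks the scope
        ("no significant weight loss", "negated"),
        ("not one bit of real pain", "affirmed"),      # beyond the 3-token window
    ])
    def test_negation_window_and_scope(self, lex, text, polarity):
        ms = annotate(text, lex, "relaxed")
        assert len(ms) == 1
        assert ms[0].polarity == polarity

    def test_post_direction_cue(self):
        lx = Lexicon(
            entries=(entry("pain"),),
            cues=(NegationCue("absent", direction="post", window=2),),
        )
        toks = tokenize("pain absent", lx)
        ms = assign_polarity(find_mentions("pain absent", lx, "strict"), toks, lx)
        assert ms[0].polarity == "negated"

    def test_determinism(self, lex):
        text = "no pain. significant weight loss. denies dyspnea."
        runs = [tuple((m.start, m.end, m.polarity) for m in annotate(text, lex, "relaxed"))
                for _ in range(3)]
        assert len(set(runs)) == 1
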