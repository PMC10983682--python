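"""Tokenization, dictionary mention finding, and negation-aware polarity.

The notes this pipeline mines mix whitespace-delimited script (English) with
unsegmented script (Thai-style running text without word boundaries).  The
tokenizer therefore has two regimes:

* letter runs made of ordinary script are split on whitespace and
  punctuation, one token per run;
* letter runs containing characters drawn from the lexicon's unsegmented
  surfaces are segmented by greedy left-to-right *maximal matching*:
  repeatedly take the longest dictionary word starting at the current
  position, falling back to single-character ``unknown`` tokens where no
  word matches.

Which characters trigger maximal matching is derived from the lexicon
itself (the alphabet of its unsegmented surfaces), so ordinary English is
never chopped up unless a user explicitly declares Latin surfaces as
unsegmented script.

Mentions are occurrences of profile-visible dictionary entries; their
polarity (affirmed vs negated) is decided by a window-based negation rule:
a pre-position cue such as "no" negates a mention within ``window`` tokens
downstream unless a scope breaker (".", ";", "but") intervenes.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass, replace

from .lexicon import Lexicon, TermEntry, normalize


@dataclass(frozen=True)
class Token:
    """A tokenizer output unit with half-open character span into the note."""

    text: str
    start: int
    end: int
    kind: str  # word | unknown | punct

    @property
    def norm(self) -> str:
        return normalize(self.text)


@dataclass(frozen=True)
class Mention:
    """A located dictionary-term occurrence with negation polarity."""

    entry: TermEntry
    start: int
    end: int
    polarity: str = "affirmed"  # affirmed | negated

    @property
    def indicator_id(self) -> int:
        return self.entry.indicator_id

    @property
    def affirmed(self) -> bool:
        return self.polarity == "affirmed"


def _char_class(ch: str) -> str:
    if ch.isspace():
        return "ws"
    if ch.isascii():
        return "latin" if (ch.isalnum() or ch == "_") else "punct"
    return "letter" if ch.isalnum() else "punct"


def _maximal_match(run: str, offset: int, surfaces: frozenset, max_len: int) -> list:
    """Greedy longest-match segmentation of one letter run.

    At each position, take the longest surface that matches (case-folded);
    a character matching nothing becomes a single-char ``unknown`` token.
    """
    tokens = []
    lowered = normalize(run)
    # normalize() can change string length for exotic codepoints; maximal
    # matching requires a 1:1 character alignment, so fall back to casefold
    # alignment only when lengths agree.
    if len(lowered) != len(run):
        lowered = run.casefold()
        if len(lowered) != len(run):
            lowered = run
    i = 0
    n = len(run)
    while i < n:
        match_len = 0
        for length in range(min(max_len, n - i), 0, -1):
            if lowered[i:i + length] in surfaces:
                match_len = length
                break
        if match_len:
            tokens.append(Token(run[i:i + match_len], offset + i, offset + i + match_len, "word"))
            i += match_len
        else:
            tokens.append(Token(run[i], offset + i, offset + i + 1, "unknown"))
            i += 1
    return tokens


def tokenize(text: str, lexicon: Lexicon) -> list:
    """Split a note into word / unknown / punct tokens.

    Token spans are non-overlapping, sorted, and cover every non-whitespace
    character, so the input can be reconstructed from tokens plus the
    skipped whitespace.
    """
    surfaces = lexicon.unsegmented_surfaces
    alphabet = lexicon.unsegmented_alphabet
    max_len = max((len(s) for s in surfaces), default=0)
    tokens: list = []
    i, n = 0, len(text)
    while i < n:
        cls = _char_class(text[i])
        j = i + 1
        while j < n and _char_class(text[j]) == cls:
            j += 1
        run = text[i:j]
        if cls == "ws":
            pass
        elif cls == "punct":
            tokens.extend(Token(ch, i + k, i + k + 1, "punct") for k, ch in enumerate(run))
        else:  # latin or letter run
            if alphabet and any(ch in alphabet for ch in normalize(run)):
                tokens.extend(_maximal_match(run, i, surfaces, max_len))
            else:
                tokens.append(Token(run, i, j, "word"))
        i = j
    return tokens


def count_words(text: str, lexicon: Lexicon) -> int:
    """Number of non-punctuation tokens in a note (the word-count filter unit)."""
    return sum(1 for t in tokenize(text, lexicon) if t.kind != "punct")


# ---------------------------------------------------------------------------
# mention finding


def _entry_token_seq(entry: TermEntry, lexicon: Lexicon) -> tuple:
    return tuple(t.norm for t in tokenize(entry.surface, lexicon) if t.kind != "punct")


def _find_token_seq(seq: tuple, norms: list) -> list:
    """All start indices where `seq` occurs as consecutive tokens."""
    hits = []
    k = len(seq)
    if k == 0:
        return hits
    first = seq[0]
    for i, t in enumerate(norms):
        if t == first and tuple(norms[i:i + k]) == seq:
            hits.append(i)
    return hits


def find_mentions(text: str, lexicon: Lexicon, profile: str,
                  tokens: list | None = None) -> list:
    """Locate every profile-visible dictionary entry in a note.

    Literal entries are matched on consecutive token sequences
    (case-insensitive after NFC); regex entries on the raw text.  Overlapping
    matches are resolved longest-first then leftmost, independently per
    indicator, so adding entries for one indicator never changes another
    indicator's mentions.  All polarities start as ``affirmed``.
    """
    view = lexicon.profile_view(profile)
    if tokens is None:
        tokens = tokenize(text, lexicon)
    norms = [t.norm for t in tokens]
    candidates: list = []
    for order, entry in enumerate(view.entries):
        if entry.match_kind == "regex":
            for m in re.finditer(entry.surface, text, flags=re.IGNORECASE):
                if m.end() > m.start():
                    candidates.append((m.start(), m.end(), order, entry))
        else:
            seq = _entry_token_seq(entry, lexicon)
            for i in _find_token_seq(seq, norms):
                start = tokens[i].start
                end = tokens[i + len(seq) - 1].end
                candidates.append((start, end, order, entry))
    # longest-first, then leftmost, per indicator
    mentions: list = []
    by_ind: dict = {}
    for start, end, order, entry in candidates:
        by_ind.setdefault(entry.indicator_id, []).append((start, end, order, entry))
    for ind in sorted(by_ind):
        kept: list = []
        for start, end, order, entry in sorted(
            by_ind[ind], key=lambda c: (-(c[1] - c[0]), c[0], c[2])
        ):
            if all(end <= ks or start >= ke for ks, ke in kept):
                kept.append((start, end))
                mentions.append(Mention(entry, start, end))
        del kept
    mentions.sort(key=lambda m: (m.start, m.end, m.indicator_id))
    return mentions


# ---------------------------------------------------------------------------
# negation


def assign_polarity(mentions: list, tokens: list, lexicon: Lexicon) -> list:
    """Mark mentions negated when a cue occurs within its window.

    A mention is negated iff some pre-direction cue ends within ``window``
    tokens before the mention's first token with no scope breaker between
    them (symmetrically for post-direction cues).  Everything else stays
    affirmed.
    """
    norms = [t.norm for t in tokens]
    starts = [t.start for t in tokens]
    breakers = {normalize(b) for b in lexicon.scope_breakers}
    is_breaker = [t in breakers for t in norms]

    # cue occurrences as (last_token_idx, first_token_idx, cue)
    pre_cues: list = []   # (end_idx, cue)
    post_cues: list = []  # (start_idx, cue)
    for cue in lexicon.cues:
        seq = tuple(t.norm for t in tokenize(cue.surface, lexicon) if t.kind != "punct")
        for i in _find_token_seq(seq, norms):
            if cue.direction == "pre":
                pre_cues.append((i + len(seq) - 1, cue))
            else:
                post_cues.append((i, cue))

    def clear_between(lo: int, hi: int) -> bool:
        """No scope breaker strictly between token indices lo and hi."""
        return not any(is_breaker[lo + 1:hi])

    out = []
    for m in mentions:
        i_first = bisect.bisect_right(starts, m.start) - 1
        # index of the token containing the mention's last character
        i_last = bisect.bisect_right(starts, m.end - 1) - 1
        negated = False
        for j, cue in pre_cues:
            if j < i_first and i_first - j <= cue.window and clear_between(j, i_first):
                negated = True
                break
        if not negated:
            for j, cue in post_cues:
                if j > i_last and j - i_last <= cue.window and clear_between(i_last, j):
                    negated = True
                    break
        out.append(replace(m, polarity="negated" if negated else "affirmed"))
    return out


def annotate(text: str, lexicon: Lexicon, profile: str) -> list:
    """tokenize → find_mentions → assign_polarity in one call."""
    tokens = tokenize(text, lexicon)
    mentions = find_mentions(text, lexicon, profile, tokens=tokens)
    return assign_polarity(mentions, tokens, lexicon)
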