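"""Term dictionaries mapping surface patterns to SPICT-LIS general indicators.

A :class:`Lexicon` bundles three kinds of knowledge used by the text-mining
pipeline:

* :class:`TermEntry` — a literal phrase or regular expression that, when found
  in a doctor's note, is evidence for one of the six SPICT-LIS general
  indicators.  Every entry belongs to one or both *rule profiles*: the
  ``strict`` profile keeps only explicit, well-defined wording (e.g.
  "significant weight loss"), while the ``relaxed`` profile adds broader
  synonyms (e.g. "weight loss", "underweight").  The strict term set is by
  construction a subset of the relaxed set.
* :class:`NegationCue` — words such as "no" or "denies" that flip a nearby
  symptom mention from affirmed to negated ("no pain").
* scope breakers — sentence or clausal terminators (".", ";", "but") that
  stop a negation cue from reaching across clause boundaries.

Lexicons are stored as TSV (one entry per line, ``#`` comments, ``#!``
directive lines for cues/breakers/segmentation words) or as JSON.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

PROFILES = ("strict", "relaxed")
INDICATOR_IDS = (1, 2, 3, 4, 5, 6)

#: Human-readable short names for the six SPICT-LIS general indicators.
INDICATOR_NAMES = {
    1: "performance status poor or deteriorating",
    2: "depends on others for care",
    3: "carer requires more help and support",
    4: "significant weight loss or remains underweight",
    5: "persistent symptoms despite best available treatment",
    6: "patient or family asks for palliative care",
}


class LexiconError(ValueError):
    """Raised when a lexicon file or entry violates the dictionary contract."""


def normalize(text: str) -> str:
    """Canonical form used for matching: Unicode NFC + casefold."""
    return unicodedata.normalize("NFC", text).casefold()


@dataclass(frozen=True)
class TermEntry:
    """One dictionary surface mapped to a general indicator.

    Parameters
    ----------
    surface
        Literal phrase or regex pattern.
    indicator_id
        SPICT-LIS general indicator 1..6 this surface is evidence for.
    profiles
        Rule profiles the entry participates in; ``strict`` implies
        ``relaxed`` (nested keyword sets).
    match_kind
        ``literal`` (matched on token sequences, case-insensitive for Latin
        script) or ``regex`` (matched on the raw note text).
    script
        ``segmented`` for whitespace-delimited script, ``unsegmented`` for
        script requiring dictionary-based maximal matching, ``either``.
    """

    surface: str
    indicator_id: int
    profiles: frozenset = frozenset({"strict", "relaxed"})
    match_kind: str = "literal"
    script: str = "segmented"
    comment: str = ""

    def __post_init__(self):
        if not self.surface:
            raise LexiconError("term surface must be non-empty")
        if self.indicator_id not in INDICATOR_IDS:
            raise LexiconError(
                f"indicator_id must be 1..6, got {self.indicator_id!r} "
                f"for surface {self.surface!r}"
            )
        object.__setattr__(self, "profiles", frozenset(self.profiles))
        unknown = self.profiles - set(PROFILES)
        if unknown:
            raise LexiconError(f"unknown profiles {sorted(unknown)} for {self.surface!r}")
        if "strict" in self.profiles and "relaxed" not in self.profiles:
            raise LexiconError(
                f"entry {self.surface!r} is strict-only: the strict term set "
                "must be a subset of the relaxed set"
            )
        if self.match_kind not in ("literal", "regex"):
            raise LexiconError(f"unknown match_kind {self.match_kind!r}")
        if self.script not in ("segmented", "unsegmented", "either"):
            raise LexiconError(f"unknown script {self.script!r}")
        if self.match_kind == "regex":
            try:
                re.compile(self.surface)
            except re.error as exc:
                raise LexiconError(
                    f"regex pattern {self.surface!r} does not compile: {exc}"
                ) from exc


@dataclass(frozen=True)
class NegationCue:
    """A negation trigger ("no", "denies") with direction and token window."""

    surface: str
    direction: str = "pre"
    window: int = 3

    def __post_init__(self):
        if not self.surface:
            raise LexiconError("negation cue surface must be non-empty")
        if self.direction not in ("pre", "post"):
            raise LexiconError(f"cue direction must be pre or post, got {self.direction!r}")
        if self.window < 1:
            raise LexiconError("cue window must be >= 1")


DEFAULT_SCOPE_BREAKERS = (".", ";", "but")


@dataclass(frozen=True)
class Lexicon:
    """A validated term dictionary with negation cues and scope breakers.

    ``segmentation_words`` are dictionary-only surfaces used solely by the
    maximal-matching tokenizer for unsegmented script; they map to no
    indicator and never produce mentions.
    """

    entries: tuple = ()
    cues: tuple = ()
    scope_breakers: tuple = DEFAULT_SCOPE_BREAKERS
    segmentation_words: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "entries", tuple(self.entries))
        object.__setattr__(self, "cues", tuple(self.cues))
        object.__setattr__(self, "scope_breakers", tuple(self.scope_breakers))
        object.__setattr__(self, "segmentation_words", tuple(self.segmentation_words))
        seen = set()
        for e in self.entries:
            key = (normalize(e.surface), e.indicator_id)
            if key in seen:
                raise LexiconError(
                    f"duplicate (surface, indicator) pair: {e.surface!r} / {e.indicator_id}"
                )
            seen.add(key)

    # -- profile handling ------------------------------------------------
    def profile_view(self, profile: str) -> "Lexicon":
        """Restrict entries to one rule profile; cues/breakers unchanged."""
        if profile not in PROFILES:
            raise LexiconError(f"unknown profile {profile!r}; expected one of {PROFILES}")
        kept = tuple(e for e in self.entries if profile in e.profiles)
        return replace(self, entries=kept)

    def entries_for(self, indicator_id: int, profile: str | None = None) -> list:
        out = [e for e in self.entries if e.indicator_id == indicator_id]
        if profile is not None:
            out = [e for e in out if profile in e.profiles]
        return out

    # -- segmentation support -------------------------------------------
    @property
    def unsegmented_surfaces(self) -> frozenset:
        """Normalized surfaces available to the maximal-matching segmenter."""
        surfs = {
            normalize(e.surface)
            for e in self.entries
            if e.match_kind == "literal" and e.script in ("unsegmented", "either")
        }
        surfs.update(normalize(w) for w in self.segmentation_words)
        return frozenset(surfs)

    @property
    def unsegmented_alphabet(self) -> frozenset:
        """Characters appearing in any unsegmented surface.

        A letter run is routed through maximal matching only when it contains
        at least one of these characters; ordinary whitespace-delimited text
        is never chopped up.
        """
        chars = set()
        for s in self.unsegmented_surfaces:
            chars.update(s)
        chars.discard(" ")
        return frozenset(chars)


# ---------------------------------------------------------------------------
# serialization

_TSV_COLUMNS = ("surface", "match_kind", "script", "indicator_id", "profiles", "comment")


def write_lexicon(lexicon: Lexicon, path) -> None:
    """Write a lexicon as TSV (``.tsv``/``.txt``) or JSON (``.json``)."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(_to_dict(lexicon), indent=2, ensure_ascii=False) + "\n",
                        encoding="utf-8")
        return
    lines = ["#\t".replace("\t", " ") + "columns: " + "\t".join(_TSV_COLUMNS)]
    lines[0] = "# columns: " + "\t".join(_TSV_COLUMNS)
    for cue in lexicon.cues:
        lines.append(f"#! cue\t{cue.surface}\t{cue.direction}\t{cue.window}")
    for brk in lexicon.scope_breakers:
        lines.append(f"#! scope_breaker\t{brk}")
    for word in lexicon.segmentation_words:
        lines.append(f"#! segmentation_word\t{word}")
    for e in lexicon.entries:
        lines.append("\t".join([
            e.surface, e.match_kind, e.script, str(e.indicator_id),
            ",".join(sorted(e.profiles)), e.comment,
        ]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _to_dict(lexicon: Lexicon) -> dict:
    return {
        "entries": [
            {
                "surface": e.surface,
                "match_kind": e.match_kind,
                "script": e.script,
                "indicator_id": e.indicator_id,
                "profiles": sorted(e.profiles),
                "comment": e.comment,
            }
            for e in lexicon.entries
        ],
        "cues": [
            {"surface": c.surface, "direction": c.direction, "window": c.window}
            for c in lexicon.cues
        ],
        "scope_breakers": list(lexicon.scope_breakers),
        "segmentation_words": list(lexicon.segmentation_words),
    }


def _from_dict(d: dict) -> Lexicon:
    entries = [
        TermEntry(
            surface=e["surface"],
            indicator_id=int(e["indicator_id"]),
            profiles=frozenset(e.get("profiles", PROFILES)),
            match_kind=e.get("match_kind", "literal"),
            script=e.get("script", "segmented"),
            comment=e.get("comment", ""),
        )
        for e in d.get("entries", [])
    ]
    cues = [
        NegationCue(c["surface"], c.get("direction", "pre"), int(c.get("window", 3)))
        for c in d.get("cues", [])
    ]
    return Lexicon(
        entries=tuple(entries),
        cues=tuple(cues),
        scope_breakers=tuple(d.get("scope_breakers", DEFAULT_SCOPE_BREAKERS)),
        segmentation_words=tuple(d.get("segmentation_words", ())),
    )


def _parse_tsv(text: str, source: str = "<string>") -> Lexicon:
    entries, cues, breakers, segwords = [], [], [], []
    saw_breaker_directive = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#!"):
            parts = line[2:].strip().split("\t")
            kind = parts[0]
            if kind == "cue":
                cues.append(NegationCue(parts[1], parts[2], int(parts[3])))
            elif kind == "scope_breaker":
                saw_breaker_directive = True
                breakers.append(parts[1])
            elif kind == "segmentation_word":
                segwords.append(parts[1])
            else:
                raise LexiconError(f"{source}:{lineno}: unknown directive {kind!r}")
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise LexiconError(
                f"{source}:{lineno}: expected columns {_TSV_COLUMNS}, got {len(fields)} fields"
            )
        surface, match_kind, script, indicator_id, profiles = fields[:5]
        comment = fields[5] if len(fields) > 5 else ""
        try:
            entry = TermEntry(
                surface=surface,
                match_kind=match_kind,
                script=script,
                indicator_id=int(indicator_id),
                profiles=frozenset(p.strip() for p in profiles.split(",") if p.strip()),
                comment=comment,
            )
        except (LexiconError, ValueError) as exc:
            raise LexiconError(f"{source}:{lineno}: {exc}") from exc
        entries.append(entry)
    return Lexicon(
        entries=tuple(entries),
        cues=tuple(cues),
        scope_breakers=tuple(breakers) if saw_breaker_directive else DEFAULT_SCOPE_BREAKERS,
        segmentation_words=tuple(segwords),
    )


def load_lexicon(path) -> Lexicon:
    """Load and validate a lexicon from a TSV or JSON file.

    Raises :class:`LexiconError` naming the offending row for strict-only
    entries, duplicate surfaces, or regex patterns that do not compile.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix == ".json":
        return _from_dict(json.loads(text))
    return _parse_tsv(text, source=str(path))


def default_lexicon() -> Lexicon:
    """The bundled English dictionary.

    Seeded from the SPICT-LIS indicator wording and the strict/relaxed
    keyword contrast for weight loss ("significant weight loss" vs
    "weight loss", "underweight", "hyposthenic build", "thinner"); the
    symptom vocabulary (pain, dyspnea, edema, delirium, xerostomia, ascites,
    dysphagia, anorexia) backs indicator 5.  Fully user-replaceable via
    :func:`load_lexicon`.
    """
    ref = resources.files("spictminer.data").joinpath("default_lexicon.tsv")
    return _parse_tsv(ref.read_text(encoding="utf-8"), source="default_lexicon.tsv")
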