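"""Preprocessing transforms and the effective lemma stream scoring consumes.

Two transcript transformations mirror the reformatting step the automated
workflow requires before lemmas are counted:

* :func:`unhide_revisions` — retraced material (``[//]`` scope) is revealed as
  plain, scoreable tokens, because a checklist item produced only inside a
  revision must still be credited.  Verbatim repetitions (``[/]`` scope)
  remain unscored.
* :func:`demote_semantic_replacements` — a semantic paraphasia coded
  ``brother [: sister] [* s:r]`` would otherwise be lemmatized as its *target*
  ("sister"), crediting a word the speaker never produced; demoting to
  ``[:: sister]`` forces the produced form to be analyzed.  Phonemic
  paraphasias keep single-colon semantics so the intended target is credited.

:func:`effective_lemmas` then yields one :class:`LemmaEvent` per credited
dictionary form, taking lemmas from an aligned ``%mor`` tier when one is
present and otherwise from :func:`analyze_surface`, a bounded fallback
analyzer driven by three editable tables (irregular inflections, clitic
contractions, dialect fusions) plus conservative regular-suffix rules.
"""

from __future__ import annotations

import copy
import enum
import logging
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .chat_io import MorWord, ReplacementStyle, ScopeRole, Transcript, select_speaker

logger = logging.getLogger(__name__)

_DATA = resources.files(__package__) / "data"


class LemmaSource(str, enum.Enum):
    MOR_TIER = "mor_tier"
    FALLBACK_ANALYZER = "fallback_analyzer"
    REPLACEMENT_TARGET = "replacement_target"


@dataclass(frozen=True)
class LemmaEvent:
    """One credited dictionary form, with where it came from."""

    lemma: str
    surface: str
    source: LemmaSource
    utterance_index: int


# ---------------------------------------------------------------------------
# Editable analyzer tables


def _read_table(name: str) -> list[list[str]]:
    rows = []
    for line in (_DATA / name).read_text(encoding="utf-8").splitlines():
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


@lru_cache(maxsize=None)
def inflection_table() -> dict[str, tuple[str, tuple[str, ...]]]:
    """surface -> (lemma, tags) for irregular forms."""
    out = {}
    for row in _read_table("inflections.tsv"):
        surface, lemma = row[0], row[1]
        tags = tuple(row[2].split(";")) if len(row) > 2 and row[2] else ()
        out[surface] = (lemma, tags)
    return out


@lru_cache(maxsize=None)
def contraction_table() -> list[tuple[str, str, str]]:
    """(suffix, expansion surface, pos), longest suffixes first."""
    rows = [(r[0], r[1], r[2] if len(r) > 2 else "x")
            for r in _read_table("contractions.tsv")]
    return sorted(rows, key=lambda r: -len(r[0]))


@lru_cache(maxsize=None)
def dialect_table() -> dict[str, tuple[str, ...]]:
    """dialect form -> component surface forms."""
    return {r[0]: tuple(r[1].split(";")) for r in _read_table("dialect.tsv")}


@lru_cache(maxsize=None)
def known_lemmas() -> frozenset[str]:
    words = {line.strip().lower()
             for line in (_DATA / "common_words.txt")
             .read_text(encoding="utf-8").splitlines()
             if line.strip() and not line.startswith("#")}
    words |= {lemma for lemma, _ in inflection_table().values()}
    return frozenset(words)


# ---------------------------------------------------------------------------
# Fallback morphological analyzer


def _clean(surface: str) -> str:
    w = surface.strip().lower()
    if "@" in w:  # CHAT special-form markers, e.g. word@c
        w = w.split("@", 1)[0]
    return w.strip("\"'()+^,;—–-") or w


def _known_candidate(*candidates: str) -> str | None:
    known = known_lemmas()
    for c in candidates:
        if len(c) >= 2 and c in known:
            return c
    return None


def _strip_plural_3s(w: str) -> tuple[str, tuple[str, ...]] | None:
    if len(w) < 3 or not w.endswith("s") or w.endswith(("ss", "us", "is")):
        return None
    cands = []
    if w.endswith("ies") and len(w) > 4:
        cands.append(w[:-3] + "y")
    if w.endswith("es"):
        cands.append(w[:-2])
    cands.append(w[:-1])
    hit = _known_candidate(*cands)
    if hit is not None:
        return hit, ("S",)
    if w.endswith("ies") and len(w) > 4:
        return w[:-3] + "y", ("S",)
    return w[:-1], ("S",)


def _strip_ed_ing(w: str) -> tuple[str, tuple[str, ...]] | None:
    # Conservative: only lemmatize -ed/-ing when the stem is a known word.
    for suffix, tag in (("ed", "PAST"), ("ing", "PRESP")):
        if not w.endswith(suffix) or len(w) < len(suffix) + 2:
            continue
        stem = w[: -len(suffix)]
        cands = [stem, stem + "e"]
        if len(stem) >= 2 and stem[-1] == stem[-2]:
            cands.append(stem[:-1])  # stopped -> stop
        if w.endswith("ied"):
            cands.append(w[:-3] + "y")  # tried -> try
        hit = _known_candidate(*cands)
        if hit is not None:
            return hit, (tag,)
    return None


def analyze_surface(surface: str) -> MorWord:
    """Analyze one orthographic word into lemma(s) and inflection tags.

    Contractions yield a main lemma plus clitic parts ("isn't" -> be + not);
    dialect fusions expand the same way ("gonna" -> go + to).  Words the
    analyzer cannot place pass through with an identity lemma.
    """
    w = _clean(surface)
    if not w:
        return MorWord(lemma=surface.lower() or "?", pos="x")

    dialect = dialect_table()
    if w in dialect:
        comps = dialect[w]
        main = analyze_surface(comps[0])
        clitics = list(main.clitic_parts)
        for comp in comps[1:]:
            sub = analyze_surface(comp)
            clitics.append((sub.lemma, sub.pos))
            clitics.extend(sub.clitic_parts)
        return MorWord(lemma=main.lemma, pos=main.pos,
                       inflection_tags=list(main.inflection_tags),
                       clitic_parts=clitics)

    irregular = inflection_table()
    if w in irregular:
        lemma, tags = irregular[w]
        return MorWord(lemma=lemma, pos="x", inflection_tags=list(tags))

    if "'" in w:
        for suffix, expansion, pos in contraction_table():
            if w.endswith(suffix) and len(w) > len(suffix):
                base = analyze_surface(w[: -len(suffix)])
                clitic_lemma = analyze_surface(expansion).lemma
                clitics = list(base.clitic_parts) + [(clitic_lemma, pos)]
                return MorWord(lemma=base.lemma, pos=base.pos,
                               inflection_tags=list(base.inflection_tags),
                               clitic_parts=clitics)

    if w not in known_lemmas():
        for rule in (_strip_plural_3s, _strip_ed_ing):
            hit = rule(w)
            if hit is not None:
                lemma, tags = hit
                return MorWord(lemma=lemma, pos="x",
                               inflection_tags=list(tags))
        logger.debug("fallback analyzer passthrough: %r", surface)
    return MorWord(lemma=w, pos="x")


# ---------------------------------------------------------------------------
# Transcript transforms


def unhide_revisions(t: Transcript) -> Transcript:
    """Reveal retraced material as plain scoreable tokens (new Transcript).

    Mirrors removing ``[//]`` revision codes so revised-then-replaced words
    are counted; ``[/]`` repetition material stays excluded.  Utterances whose
    material changed lose their stored ``%mor`` tier (it described the
    pre-transform text), sending them to the fallback analyzer downstream.
    Idempotent.
    """
    out = copy.deepcopy(t)
    for utt in out.utterances:
        changed = False
        for tok in utt.tokens:
            if tok.scope_role is ScopeRole.RETRACE_MATERIAL:
                tok.scope_role = ScopeRole.PLAIN
                tok.scope_group = None
                changed = True
        if changed and utt.mor is not None:
            utt.mor = None
            utt.warnings.append("mor dropped: retraces unhidden")
    return out


def demote_semantic_replacements(t: Transcript) -> Transcript:
    """Switch semantic-paraphasia targets to double-colon style (new copy).

    Single-colon replacements carrying a semantic error class (``s:...``)
    become double-colon so the produced form, not the unsaid target, is
    credited.  Phonological classes (``p:...``) keep the target.  Untyped
    replacements are left alone with a logged notice.  Idempotent.
    """
    out = copy.deepcopy(t)
    for utt in out.utterances:
        changed = False
        for tok in utt.tokens:
            if tok.replacement_style is not ReplacementStyle.SINGLE_COLON:
                continue
            if any(code.startswith("s") for code in tok.error_codes):
                tok.replacement_style = ReplacementStyle.DOUBLE_COLON
                changed = True
            elif not tok.error_codes:
                logger.debug("untyped replacement kept single-colon: %r",
                             tok.surface)
        if changed and utt.mor is not None:
            utt.mor = None
            utt.warnings.append("mor dropped: semantic replacement demoted")
    return out


def reformat(t: Transcript) -> Transcript:
    """Both preprocessing transforms, in the workflow's order."""
    return demote_semantic_replacements(unhide_revisions(t))


# ---------------------------------------------------------------------------
# Effective lemma stream


def effective_lemmas(t: Transcript, speaker: str = "PAR",
                     task: str | None = None) -> list[LemmaEvent]:
    """The ordered lemma stream scoring consumes, for one speaker (and task).

    Expects a transcript already passed through :func:`reformat`.  Fillers,
    unintelligible tokens and repetition material yield nothing; retrace
    material still marked as such (un-reformatted input) is likewise skipped,
    matching what a morphology tier would parse.  Double-colon replacements
    credit the produced surface form, single-colon replacements the intended
    target.  Contractions and dialect fusions expand to multiple events.
    """
    if task is not None:
        from .chat_io import extract_task_segment
        t = extract_task_segment(t, task)
    code = speaker.strip().upper()
    events: list[LemmaEvent] = []
    for ui, utt in enumerate(t.utterances):
        if utt.speaker.strip().upper() != code:
            continue
        scoreable = utt.scoreable_tokens()
        if utt.mor is not None and len(utt.mor) == len(scoreable):
            for tok, mw in zip(scoreable, utt.mor):
                for lemma in mw.lemmas():
                    events.append(LemmaEvent(lemma=lemma.lower(),
                                             surface=tok.surface,
                                             source=LemmaSource.MOR_TIER,
                                             utterance_index=ui))
            continue
        for tok in utt.tokens:
            if not tok.is_scoreable:
                continue
            if tok.replacement_style is ReplacementStyle.SINGLE_COLON:
                form = tok.replacement_target or tok.surface
                source = LemmaSource.REPLACEMENT_TARGET
            else:
                form = tok.surface
                source = LemmaSource.FALLBACK_ANALYZER
            mw = analyze_surface(form)
            for lemma in mw.lemmas():
                events.append(LemmaEvent(lemma=lemma.lower(),
                                         surface=tok.surface,
                                         source=source,
                                         utterance_index=ui))
    return events


def analysis_lemmas(form: str) -> frozenset[str]:
    """All lemmas one surface form contributes (main + clitic expansions)."""
    return frozenset(lem.lower() for lem in analyze_surface(form).lemmas())
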