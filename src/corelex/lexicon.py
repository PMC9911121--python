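"""Core-lexicon checklists: representation, loading, validation, matching.

A core lexicon is a normed checklist of lexical items typically produced in
response to one elicitation task; a sample scores 1 per item present at least
once.  Checklists are shipped as editable UTF-8 tab-separated files, one per
task, with columns ``label | accepted_lemmas (;-separated) | extended_forms``
and ``# task_id`` / ``# provenance`` comment headers.

The five packaged lists are SYNTHETIC reconstructions: the validation study
takes its lists from cited norming publications that are not redistributed
here, so these fixtures carry plausible item counts and the documented
synonym exceptions (mother/mom/mama, father/dad/pa) but must not be treated
as authoritative norms.  Every score records the checklist hash so results
are traceable to a specific list version.
"""

from __future__ import annotations

import csv
import hashlib
import io
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from .errors import LexiconValidationError
from .normalize import LemmaEvent
from .tasks import CANONICAL_TASKS

_LEXDIR = resources.files(__package__) / "data" / "lexicons"


@dataclass(frozen=True)
class LexiconItem:
    """One checklist entry: head lemma plus the lemma group that credits it."""

    label: str
    accepted_lemmas: frozenset[str]
    extended_forms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.accepted_lemmas:
            raise LexiconValidationError(f"item {self.label!r}: empty lemma group")
        if self.label not in self.accepted_lemmas:
            raise LexiconValidationError(
                f"item {self.label!r}: label not in its accepted lemmas")


@dataclass(frozen=True)
class CoreLexicon:
    task_id: str
    items: tuple[LexiconItem, ...]
    provenance: str = ""
    source_hash: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.items:
            raise LexiconValidationError(f"{self.task_id}: empty checklist")

    def __len__(self) -> int:
        return len(self.items)

    @property
    def labels(self) -> list[str]:
        return [item.label for item in self.items]

    def accepted_union(self) -> frozenset[str]:
        out: set[str] = set()
        for item in self.items:
            out |= item.accepted_lemmas
        return frozenset(out)

    @property
    def hash(self) -> str:
        """Stable short digest of the checklist content (version stamp)."""
        canon = self.task_id + "\n" + "\n".join(
            f"{i.label}|{','.join(sorted(i.accepted_lemmas))}"
            f"|{','.join(sorted(i.extended_forms))}"
            for i in self.items)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def matches(item: LexiconItem, ev: LemmaEvent) -> bool:
    """True iff a lemma event credits this checklist item.

    Matching is by dictionary form only: part of speech and meaning in
    context are deliberately ignored ("hand" the noun and "hand" the verb
    both count), and synonyms outside the accepted group do not match.
    User-supplied extended forms match on the raw surface.
    """
    return (ev.lemma.lower() in item.accepted_lemmas
            or ev.surface.lower() in item.extended_forms)


def _validate(task_id: str, rows: list[tuple[str, set[str], set[str]]],
              provenance: str, source_hash: str) -> CoreLexicon:
    seen: set[str] = set()
    items: list[LexiconItem] = []
    claimed: dict[str, str] = {}
    for rownum, (label, lemmas, forms) in enumerate(rows, start=1):
        for entry in [label, *lemmas, *forms]:
            if entry != entry.lower():
                raise LexiconValidationError(
                    f"{task_id} row {rownum}: entry {entry!r} is not lowercase")
        if label in seen:
            raise LexiconValidationError(
                f"{task_id} row {rownum}: duplicate label {label!r}")
        seen.add(label)
        for lemma in lemmas:
            if lemma in claimed:
                raise LexiconValidationError(
                    f"{task_id} row {rownum}: lemma {lemma!r} already credits "
                    f"item {claimed[lemma]!r}; accepted groups must be disjoint")
            claimed[lemma] = label
        items.append(LexiconItem(label=label,
                                 accepted_lemmas=frozenset(lemmas),
                                 extended_forms=frozenset(forms)))
    return CoreLexicon(task_id=task_id, items=tuple(items),
                       provenance=provenance, source_hash=source_hash)


def parse_lexicon(text: str, default_task_id: str = "custom") -> CoreLexicon:
    """Parse checklist file content; see module docstring for the format."""
    task_id = default_task_id
    provenance = ""
    body: list[str] = []
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            key = key.strip().lower()
            if key == "task_id":
                task_id = value.strip()
            elif key == "provenance":
                provenance = value.strip()
            continue
        if line.strip():
            body.append(line)
    rows: list[tuple[str, set[str], set[str]]] = []
    reader = csv.reader(io.StringIO("\n".join(body)), delimiter="\t")
    for raw in reader:
        if not raw or not raw[0].strip():
            continue
        if raw[0].strip().lower() == "label":  # column header row
            continue
        label = raw[0].strip()
        lemmas = {s.strip() for s in (raw[1] if len(raw) > 1 else "").split(";")
                  if s.strip()} or {label}
        forms = {s.strip() for s in (raw[2] if len(raw) > 2 else "").split(";")
                 if s.strip()}
        rows.append((label, lemmas, forms))
    if not rows:
        raise LexiconValidationError(f"{task_id}: checklist has no items")
    digest = hashlib.sha256(text.encode()).hexdigest()[:12]
    return _validate(task_id, rows, provenance, digest)


def load_lexicon(path) -> CoreLexicon:
    """Load and validate one checklist file."""
    with open(path, encoding="utf-8") as fh:
        return parse_lexicon(fh.read())


@lru_cache(maxsize=None)
def builtin_lexicon(task_id: str) -> CoreLexicon:
    """The packaged (synthetic stand-in) checklist for one canonical task."""
    from .tasks import resolve_task
    canon = resolve_task(task_id)
    if canon is None:
        raise LexiconValidationError(
            f"no builtin checklist for task {task_id!r}; "
            f"known tasks: {', '.join(CANONICAL_TASKS)}")
    text = (_LEXDIR / f"{canon.lower()}.tsv").read_text(encoding="utf-8")
    return parse_lexicon(text, default_task_id=canon)


def builtin_tasks() -> dict[str, CoreLexicon]:
    """All five packaged task checklists, keyed by canonical task id."""
    return {task: builtin_lexicon(task) for task in CANONICAL_TASKS}
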