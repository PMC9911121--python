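"""The scoring engine: checklist scores for lemma streams, files and folders.

Composes the pipeline the automated workflow prescribes: parse the CHAT file,
reveal retraced material, demote semantic-paraphasia targets, keep only the
participant's utterances for the requested task, lemmatize, then mark each
checklist item 1 if any lemma credits it.  Scores are frequency-invariant
(three "mother"s still score 1) and every score carries the checklist hash.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .chat_io import read_chat, Transcript
from .errors import CorelexError
from .lexicon import CoreLexicon, matches
from .normalize import LemmaEvent, effective_lemmas, reformat

logger = logging.getLogger(__name__)

_FIXED_COLUMNS = ("sample_id", "task")


@dataclass
class ChecklistScore:
    """Binary presence vector and total for one sample x one task."""

    sample_id: str
    task_id: str
    per_item: dict[str, int]
    lexicon_hash: str = ""

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.per_item.items() if v not in (0, 1)}
        if bad:
            raise ValueError(f"per_item values must be 0/1, got {bad}")

    @property
    def total(self) -> int:
        return sum(self.per_item.values())


@dataclass
class ScoreTable:
    """Ordered score rows for one task, round-trippable through CSV."""

    rows: list[ChecklistScore] = field(default_factory=list)
    task_id: str = ""

    def __post_init__(self) -> None:
        keys = [(r.sample_id, r.task_id) for r in self.rows]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (sample_id, task) rows in ScoreTable")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.rows]

    @property
    def totals(self) -> list[int]:
        return [r.total for r in self.rows]

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for r in self.rows:
            rec = {"sample_id": r.sample_id, "task": r.task_id,
                   **r.per_item, "total": r.total,
                   "lexicon_hash": r.lexicon_hash}
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ScoreTable":
        item_cols = [c for c in df.columns
                     if c not in _FIXED_COLUMNS + ("total", "lexicon_hash")]
        rows = []
        for _, rec in df.iterrows():
            rows.append(ChecklistScore(
                sample_id=str(rec["sample_id"]),
                task_id=str(rec.get("task", "")),
                per_item={c: int(rec[c]) for c in item_cols},
                lexicon_hash=str(rec.get("lexicon_hash", "") or "")))
        task = rows[0].task_id if rows else ""
        return cls(rows=rows, task_id=task)

    @classmethod
    def read_csv(cls, path) -> "ScoreTable":
        return cls.from_dataframe(pd.read_csv(path, keep_default_na=False))


def score_lemmas(events: list[LemmaEvent], lex: CoreLexicon,
                 sample_id: str = "sample") -> ChecklistScore:
    """Score a lemma stream: item -> 1 iff at least one event matches it."""
    per_item = {
        item.label: int(any(matches(item, ev) for ev in events))
        for item in lex.items
    }
    return ChecklistScore(sample_id=sample_id, task_id=lex.task_id,
                          per_item=per_item, lexicon_hash=lex.hash)


def score_transcript(t: Transcript, lex: CoreLexicon, speaker: str = "PAR",
                     task: str | None = None,
                     sample_id: str = "sample") -> ChecklistScore:
    """Full pipeline on an in-memory transcript.

    ``task=None`` scores the whole transcript (single-task files); otherwise
    the task's gem segment is extracted and a missing task raises.
    """
    events = effective_lemmas(reformat(t), speaker=speaker, task=task)
    return score_lemmas(events, lex, sample_id=sample_id)


def score_file(path, lex: CoreLexicon, speaker: str = "PAR",
               task: str | None = None) -> ChecklistScore:
    """Parse and score one .cha file; errors carry the file name."""
    path = Path(path)
    try:
        t = read_chat(path)
        return score_transcript(t, lex, speaker=speaker, task=task,
                                sample_id=path.stem)
    except CorelexError as err:
        raise type(err)(f"{path.name}: {err}") from err


def batch_score(folder, lex: CoreLexicon, speaker: str = "PAR",
                task: str | None = None, pattern: str = "*.cha") -> ScoreTable:
    """Score every matching file in a folder into one table.

    Files are processed in sorted name order; files that fail to parse are
    reported to the log and skipped.  Zero matching files is an error.
    """
    folder = Path(folder)
    paths = sorted(folder.glob(pattern))
    if not paths:
        raise CorelexError(f"no files matching {pattern!r} in {folder}")
    rows: list[ChecklistScore] = []
    skipped: list[tuple[str, str]] = []
    for path in paths:
        try:
            rows.append(score_file(path, lex, speaker=speaker, task=task))
        except CorelexError as err:
            logger.warning("skipping %s: %s", path.name, err)
            skipped.append((path.name, str(err)))
    logger.info("batch_score: %d scored, %d skipped", len(rows), len(skipped))
    table = ScoreTable(rows=rows, task_id=lex.task_id)
    table.skipped = skipped  # type: ignore[attr-defined]
    return table
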