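"""Synthetic CHAT fixtures with exact, known ground-truth checklist scores.

Real validation corpora for this method are membership-gated, so the test
bed is generated: each transcript contains a Bernoulli-selected subset of
checklist items (randomly inflected), distractor words that can credit no
item, fillers, retraces and repetitions, coded semantic and phonemic
paraphasias, and dialect fusions — the phenomena the scoring rules exist
for.  The generator records, per emitted token, exactly which dictionary
forms a correct scorer must credit, so the returned ground truth is
computed from the construction itself and never by running the engine.

A simulated manual scorer flips credited items to omissions at a configured
rate, matching the observed profile of hand-scoring error (omissions of
items that were in fact produced).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .chat_io import (Gem, ReplacementStyle, ScopeRole, Token, Transcript,
                      Utterance, write_chat_file)
from .lexicon import CoreLexicon, LexiconItem, builtin_lexicon
from .normalize import (analysis_lemmas, analyze_surface, dialect_table,
                        inflection_table, known_lemmas)
from .scoring import ChecklistScore, ScoreTable

_FILLERS = ("&-um", "&-uh", "&=laughs", "&-er")


@dataclass(frozen=True)
class GenerationConfig:
    """Parameters of the synthetic transcript generator.

    Rates are per produced checklist-item token unless noted.  Defaults
    emulate a mildly disfluent narrative sample: most checklist items
    produced, occasional revisions/repetitions, rare coded paraphasias.
    """

    task_id: str = "BrokenWindow"
    coverage: float = 0.6
    n_fillers: int = 4
    retrace_rate: float = 0.06
    repetition_rate: float = 0.06
    semantic_paraphasia_rate: float = 0.03
    phonemic_paraphasia_rate: float = 0.03
    dialect_rate: float = 0.08
    distractor_vocab_size: int = 40
    include_mor: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("coverage", "retrace_rate", "repetition_rate",
                     "semantic_paraphasia_rate", "phonemic_paraphasia_rate",
                     "dialect_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class _Emission:
    """One planned stretch of tokens plus the lemmas it must credit."""

    tokens: list[Token]
    lemmas: frozenset[str] = frozenset()
    surfaces: frozenset[str] = frozenset()


def _distractor_pool(lex: CoreLexicon, size: int,
                     rng: np.random.Generator) -> list[str]:
    accepted = lex.accepted_union()
    extended = {f for item in lex.items for f in item.extended_forms}
    pool = [w for w in sorted(known_lemmas())
            if w not in extended and not (analysis_lemmas(w) & accepted)]
    if len(pool) > size:
        idx = rng.choice(len(pool), size=size, replace=False)
        pool = [pool[i] for i in sorted(idx)]
    return pool


def _inflected_form(lemma: str, rng: np.random.Generator) -> str:
    """A surface realization of a lemma that still lemmatizes back to it."""
    candidates = [lemma]
    for surface, (lem, _tags) in inflection_table().items():
        if lem == lemma:
            candidates.append(surface)
    for suffix in ("s", "es", "ed", "ing"):
        candidates.append(lemma + suffix)
    valid = [c for c in candidates if lemma in analysis_lemmas(c)]
    return valid[int(rng.integers(len(valid)))]


def _reverse_dialect() -> dict[str, str]:
    out: dict[str, str] = {}
    for form, comps in dialect_table().items():
        primary = analyze_surface(comps[0]).lemma
        out.setdefault(primary, form)
    return out


def _distort(form: str, lex: CoreLexicon) -> str:
    """A phonemically-close nonword that credits nothing on the checklist."""
    accepted = lex.accepted_union()
    for letter in "bdfgkmnprstvz":
        cand = letter + form[1:]
        if cand != form and not (analysis_lemmas(cand) & accepted):
            return cand
    return "z" + form


def generate_transcript(cfg: GenerationConfig, lex: CoreLexicon | None = None,
                        sample_id: str = "sample"
                        ) -> tuple[Transcript, ChecklistScore]:
    """One parseable transcript plus its exact ground-truth score.

    Ground truth credits an item iff some emitted participant token (outside
    repetition scope) contributes a lemma in the item's accepted group —
    including retraced material (scoreable after reformatting), phonemic-
    paraphasia targets, and dialect components — and never credits semantic-
    paraphasia targets the speaker did not actually produce.
    """
    if lex is None:
        lex = builtin_lexicon(cfg.task_id)
    rng = np.random.default_rng(cfg.seed)
    distractors = _distractor_pool(lex, cfg.distractor_vocab_size, rng)
    if not distractors:
        raise ValueError("no distractor vocabulary disjoint from the checklist")
    rev_dialect = _reverse_dialect()
    gid_counter = iter(range(10_000))

    def draw_distractor() -> str:
        return distractors[int(rng.integers(len(distractors)))]

    emissions: list[_Emission] = []

    for item in lex.items:
        if rng.random() >= cfg.coverage:
            continue
        lemma = sorted(item.accepted_lemmas)[
            int(rng.integers(len(item.accepted_lemmas)))]
        form = _inflected_form(lemma, rng)
        roll = rng.random()
        if roll < cfg.semantic_paraphasia_rate:
            produced = draw_distractor()
            tok = Token(surface=produced, replacement_target=form,
                        replacement_style=ReplacementStyle.SINGLE_COLON,
                        error_codes=["s:r"])
            lemmas = analysis_lemmas(produced)
        elif roll < cfg.semantic_paraphasia_rate + cfg.phonemic_paraphasia_rate:
            produced = _distort(form, lex)
            tok = Token(surface=produced, replacement_target=form,
                        replacement_style=ReplacementStyle.SINGLE_COLON,
                        error_codes=["p:n"])
            lemmas = analysis_lemmas(form)
        elif (roll < cfg.semantic_paraphasia_rate + cfg.phonemic_paraphasia_rate
              + cfg.dialect_rate and lemma in rev_dialect):
            produced = rev_dialect[lemma]
            tok = Token(surface=produced)
            lemmas = analysis_lemmas(produced)
        else:
            tok = Token(surface=form)
            lemmas = analysis_lemmas(form)

        tokens = [tok]
        surfaces = frozenset({tok.surface.lower()})
        plain = (tok.replacement_style is ReplacementStyle.NONE)
        if plain and rng.random() < cfg.retrace_rate:
            # Item produced inside a revision, then replaced by a distractor:
            # still scoreable once revisions are unhidden.
            tok.scope_role = ScopeRole.RETRACE_MATERIAL
            tok.scope_group = next(gid_counter)
            revision = draw_distractor()
            tokens.append(Token(surface=revision))
            lemmas = lemmas | analysis_lemmas(revision)
            surfaces = surfaces | {revision.lower()}
        elif plain and rng.random() < cfg.repetition_rate:
            # Verbatim repetition: first copy unscored, second plain.
            first = Token(surface=tok.surface,
                          scope_role=ScopeRole.REPETITION_MATERIAL,
                          scope_group=next(gid_counter))
            tokens = [first, tok]
        emissions.append(_Emission(tokens=tokens, lemmas=frozenset(lemmas),
                                   surfaces=surfaces))

    n_distractor_tokens = max(3, len(lex.items) // 2)
    for _ in range(n_distractor_tokens):
        word = draw_distractor()
        emissions.append(_Emission(tokens=[Token(surface=word)],
                                   lemmas=analysis_lemmas(word),
                                   surfaces=frozenset({word.lower()})))
    for _ in range(cfg.n_fillers):
        filler = _FILLERS[int(rng.integers(len(_FILLERS)))]
        emissions.append(_Emission(
            tokens=[Token(surface=filler, is_filler=True)]))

    order = rng.permutation(len(emissions))
    emissions = [emissions[i] for i in order]

    # Ground truth from the construction (no engine involved).
    per_item: dict[str, int] = {}
    for item in lex.items:
        hit = any(em.lemmas & item.accepted_lemmas
                  or em.surfaces & item.extended_forms
                  for em in emissions)
        per_item[item.label] = int(hit)
    truth = ChecklistScore(sample_id=sample_id, task_id=lex.task_id,
                           per_item=per_item, lexicon_hash=lex.hash)

    utterances = [Utterance(speaker="INV",
                            tokens=[Token(surface=w) for w in
                                    "okay now tell me what happened".split()],
                            terminator=".")]
    i = 0
    while i < len(emissions):
        target = int(rng.integers(4, 10))
        toks: list[Token] = []
        while i < len(emissions) and (not toks or
                                      len(toks) + len(emissions[i].tokens)
                                      <= target):
            toks.extend(emissions[i].tokens)
            i += 1
        utt = Utterance(speaker="PAR", tokens=toks, terminator=".")
        if cfg.include_mor and all(
                t.scope_role is ScopeRole.PLAIN
                and t.replacement_style is ReplacementStyle.NONE
                and not t.is_unintelligible
                for t in toks):
            utt.mor = [analyze_surface(t.surface)
                       for t in toks if not t.is_filler]
        utterances.append(utt)

    t = Transcript(
        headers=[("Languages", "eng"),
                 ("Participants", "PAR Participant, INV Investigator"),
                 ("ID", f"eng|synthetic|PAR|||||Participant|{sample_id}||")],
        utterances=utterances,
        gems=[Gem(label=lex.task_id, start=0, end=len(utterances),
                  style="G")])
    return t, truth


def generate_corpus(n: int, cfg: GenerationConfig,
                    lex: CoreLexicon | None = None, out_dir=None,
                    coverage_range: tuple[float, float] | None = (0.30, 0.90),
                    ) -> tuple[list[tuple[str, Transcript]], ScoreTable]:
    """A corpus of n transcripts with per-file seeds and a truth table.

    Per-transcript coverage is drawn uniformly from ``coverage_range`` to
    emulate the ability spread of a mixed participant sample (pass ``None``
    to use ``cfg.coverage`` for every transcript).  With ``out_dir`` set,
    writes ``sample_###.cha`` files plus ``truth.csv`` and returns the same
    objects.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if lex is None:
        lex = builtin_lexicon(cfg.task_id)
    master = np.random.default_rng(cfg.seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n)
    coverages = (master.uniform(*coverage_range, size=n)
                 if coverage_range is not None
                 else np.full(n, cfg.coverage))
    out: list[tuple[str, Transcript]] = []
    rows: list[ChecklistScore] = []
    for i in range(n):
        sample_id = f"sample_{i:03d}"
        sub = replace(cfg, seed=int(child_seeds[i]),
                      coverage=float(coverages[i]))
        t, truth = generate_transcript(sub, lex, sample_id=sample_id)
        out.append((sample_id, t))
        rows.append(truth)
    truth_table = ScoreTable(rows=rows, task_id=lex.task_id)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sample_id, t in out:
            write_chat_file(t, out_dir / f"{sample_id}.cha")
        truth_table.to_csv(out_dir / "truth.csv")
    return out, truth_table


def simulate_manual_scorer(truth: ScoreTable, omission_rate: float,
                           seed: int = 0) -> ScoreTable:
    """A hand scorer that only makes omission errors.

    Each credited cell (value 1) is independently flipped to 0 with
    probability ``omission_rate``; absent items are never spuriously
    credited, matching the observed error profile of trained hand scorers.
    """
    if not 0.0 <= omission_rate <= 1.0:
        raise ValueError("omission_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for r in truth.rows:
        per_item = {label: (0 if v == 1 and rng.random() < omission_rate
                            else v)
                    for label, v in r.per_item.items()}
        rows.append(ChecklistScore(sample_id=r.sample_id, task_id=r.task_id,
                                   per_item=per_item,
                                   lexicon_hash=r.lexicon_hash))
    return ScoreTable(rows=rows, task_id=truth.task_id)
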