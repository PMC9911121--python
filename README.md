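# corelex

Automated core-lexicon (CoreLex) scoring of CHAT discourse transcripts,
with the reliability machinery needed to validate automated against manual
scoring.

## The problem

Core lexicon analysis measures the *typicality* of word choice in
structured, monologic discourse — a person retells a story or explains a
procedure, and the sample is checked against a normed checklist of the
lexical items speakers typically produce for that prompt. Each checklist
item scores 1 if produced at least once and 0 otherwise, so a sample's
CoreLex score for task *t* with checklist *L(t)* is

```
score = Σ_{w ∈ L(t)} 1[ w produced at least once ]
```

where "produced" accepts the word's plurals, conjugations and other
inflections, contracted forms ("isn't" credits *be* and *not*), and
dialect fusions ("gonna" credits *go* and *to*) — but not synonyms
("lad" never credits *boy*), with a documented exception for family terms
(*mother/mom/mama*, *father/dad/pa*). Matching ignores part of speech and
meaning in context.

Hand-scoring this from transcripts is slow and error-prone. This package
automates it for transcripts in CHAT (TalkBank) format, for the five
standard elicitation tasks (Broken Window, Cat Rescue, Cinderella, Refused
Umbrella, Sandwich) or any user-supplied checklist. It is aimed at aphasia
researchers and speech-language pathologists who already transcribe
discourse samples.

## What it does

1. **Parse** the CHAT subset the method needs: speaker tiers, `%mor`
   morphology tiers, gem task markers, target replacements `[: word]` /
   `[:: word]`, error codes `[* s:r]`, retraces `[//]`, repetitions `[/]`,
   fillers and unintelligible tokens (`corelex.chat_io`).
2. **Reformat** before scoring (`corelex.normalize`): retraced material is
   revealed (a checklist word produced only in a revision still counts) and
   semantic-paraphasia replacements are demoted to `[:: ]` so the word the
   speaker actually said — not the unsaid target — is credited. Phonemic
   paraphasias keep `[: ]` semantics and credit the intended target.
3. **Lemmatize** from the `%mor` tier when present, otherwise with a
   bounded fallback analyzer driven by editable tables (irregular
   inflections, contractions, dialect forms).
4. **Score** against a checklist; results land in a spreadsheet-ready CSV
   stamped with the checklist version hash (`corelex.scoring`,
   `corelex.lexicon`).
5. **Validate**: two-way random absolute-agreement ICC with 95% CI and
   interpretation bands (poor/moderate/good/excellent at .5/.75/.9), an
   item-level discrepancy audit between two scorings, and error
   proportions (`corelex.reliability`).
6. **Generate fixtures**: synthetic transcripts with exact ground-truth
   scores and a simulated omission-only hand scorer
   (`corelex.synthetic`), so the whole pipeline is testable without access
   to gated clinical corpora.

The packaged checklists are clearly-labelled synthetic stand-ins with
realistic item counts (24–94 items per task); replace them with your own
lists via `--lexicon` / `load_lexicon()` for real analyses.

## Worked example

```python
import corelex as cx

text = ("*PAR:\t&-um the boy <is going> [//] was gonna kick .\n"
        "*PAR:\ttick [: kick] [* p:n] the ball through the window .\n")
t = cx.reformat(cx.parse_chat(text))
events = cx.effective_lemmas(t, "PAR")
print([e.lemma for e in events])
score = cx.score_lemmas(events, cx.builtin_lexicon("BrokenWindow"), "demo")
print(score.total, {k: v for k, v in score.per_item.items() if v})
```

prints

```
['the', 'boy', 'be', 'go', 'be', 'go', 'to', 'kick', 'kick', 'the', 'ball', 'through', 'the', 'window']
9 {'ball': 1, 'be': 1, 'boy': 1, 'go': 1, 'kick': 1, 'the': 1, 'through': 1, 'to': 1, 'window': 1}
```

The filler is ignored; the retraced "is going" is revealed and credits
*be* and *go*; "gonna" credits both *go* and *to*; the phonemic paraphasia
"tick" credits its target *kick*; "kick" produced twice still scores 1.
The total, 9, is the number of Broken Window checklist items present.

The same workflow from the shell:

```
corelex reformat session.cha                 # writes session.corelex.cha
corelex score folder/ --task CatRescue --out scores.csv
corelex reliability engine.csv manual.csv    # ICC + discrepancy audit
corelex synth --task Cinderella -n 48 --seed 7 --out-dir corpus/
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the full pipeline from scratch: for each of the five tasks it
generates a 48-sample synthetic corpus, batch-scores the written `.cha`
files with the engine, simulates a hand scorer with a 3% omission rate,
and prints the inter-method ICC (with CI and band) plus the discrepancy
audit, then writes the JSON result map to `--out`.
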