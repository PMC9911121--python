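# Methods

## The measure

A core lexicon (CoreLex) checklist lists the lexical items speakers
typically produce for one structured discourse prompt. A sample's score is
the count of checklist items present at least once in the participant's
speech for that task. Scoring is binary per item and frequency-invariant;
matching is by dictionary form (lemma), blind to part of speech and
meaning in context.

## Matching semantics

An item is credited when any effective lemma of the participant's speech
falls in the item's *accepted lemma group*:

- **Inflections.** Plurals, conjugations and other inflections credit the
  base form (*went, going, goes* → *go*).
- **Contractions.** Clitics detach and count as their full forms
  (*isn't* → *be* + *not*).
- **Dialect fusions.** Standard-English components each count
  (*gonna* → *go* + *to*).
- **Synonyms** never credit, except the family-term groups shipped on the
  checklists themselves (*mother/mom/mama/mommy*, *father/dad/daddy/papa/pa*).
- **Semantic paraphasias** (`brother [: sister] [* s:r]`): the produced
  word is credited, not the unsaid target; the reformatting step rewrites
  the code to `[:: sister]`, which blocks target substitution.
- **Phonemic paraphasias** (`tick [: kick] [* p:n]`): the intended target
  is credited. Whether a distortion qualifies for a target code is a
  transcription-time judgement; this package trusts the transcriber's
  coding and computes no phoneme overlap.
- **Retraces** (`[//]` scope) are revealed before scoring — an item
  produced only inside a revision still counts. **Repetitions** (`[/]`
  scope) are verbatim restarts and are never credited from their scoped
  copy. **Fillers** (`&-um`) and **unintelligible** tokens (`xxx`) are
  ignored.
- A single-colon replacement with *no* error class keeps target semantics
  (the target is credited) with a logged notice: untyped replacements in
  practice are overwhelmingly non-semantic, and demoting them would
  silently discredit correctly-coded targets. Users who disagree can
  pre-code their transcripts.

## Lemmatization

When an utterance carries a `%mor` tier whose entries align with its
parseable tokens, lemmas are taken from it directly (the tier already
encodes replacement semantics). Otherwise a fallback analyzer applies, in
order: a dialect/fusion table, an irregular-inflection table, clitic
detachment, then conservative regular-suffix rules (-s/-es/-ies,
-ed/-ied, -ing). Suffix stripping consults a packaged known-word list to
disambiguate stems (*horses* → *horse*, not *hors*); -ed/-ing strip only
when a known stem results, so unknown vocabulary passes through with an
identity lemma rather than being mangled. All four tables are editable
UTF-8 text files under `src/corelex/data/`.

Known analyzer limitations: possessive *'s* is read as the *be* clitic
(MOR distinguishes these; the fallback cannot), and novel compounds
("kittycat") pass through unanalyzed — checklists can catch these via
per-item `extended_forms`, which match on the raw surface.

After either reformatting transform changes an utterance's material, its
stored `%mor` tier is dropped (it described the pre-transform text); those
utterances are lemmatized by the fallback analyzer. This stands in for
re-running the MOR grammar, which is out of scope.

## Checklists

One tab-separated file per task: `label`, `accepted_lemmas` (;-separated),
`extended_forms`, with `# task_id` and `# provenance` headers. Validation
enforces lowercase entries, unique labels, and **disjoint** accepted
groups — binary per-item scoring is ill-defined if one production could
credit two items. Every score row carries a 12-hex-digit hash of the
checklist file, and the reliability tools refuse to compare tables scored
against different checklist versions.

The five packaged lists are synthetic stand-ins (the real normed lists are
not redistributable here). Item counts — Broken Window 24, Sandwich 25,
Cat Rescue 34, Refused Umbrella 35, Cinderella 94 — were fixed to be
consistent with the error-proportion arithmetic reported for the method's
validation corpora, but the word inventories are plausible reconstructions
only and must not be used as norms.

## Reliability

`icc_two_way_random_agreement` computes ICC(2,1): samples and scoring
methods both random, absolute agreement, single measures — the design in
which each transcript is scored once per modality. From the two-way ANOVA
mean squares (n samples × k methods),

```
ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)
```

with the 95% CI from the F-based method for this model (the McGraw–Wong
formulation); all mean squares are returned for audit. Average measures
ICC(2,k) sits behind `average=True`, with CI bounds mapped through the
Spearman–Brown-type transform `L·k / (1 + (k−1)·L)`; that transform is
singular for strongly negative single-measure bounds, so bounds are
clamped to bracket the point estimate. A matrix with zero variance
anywhere relevant (all cells equal, or zero method and error variance) is
perfect agreement by convention: ICC = 1 with a degenerate CI, flagged.
Interpretation bands are left-closed at .5 / .75 / .9
(poor/moderate/good/excellent).

`compare_modalities` lists every (sample, item) cell where two scorings
disagree, with direction, and `error_proportion` reports
`#errors / (#items × #samples)`.

## Synthetic generator

`generate_transcript` emits a parseable CHAT transcript whose ground-truth
score is exact *by construction*: every emitted token records which lemmas
a correct scorer must credit, and truth is computed from that record, never
by running the engine. Contents per transcript:

- a Bernoulli(coverage) subset of checklist items, each realized as a
  randomly chosen inflection of a randomly chosen accepted lemma;
- distractor tokens drawn from a packaged vocabulary filtered so that no
  distractor's analysis can credit any checklist item;
- fillers, retraces (item revealed-in-revision followed by a distractor
  "correction"), verbatim repetitions, coded semantic and phonemic
  paraphasias, and dialect fusions;
- `%mor` tiers on utterances without inline codes (exercising the mor
  path) and none on coded utterances (exercising the fallback path);
- an investigator turn, excluded by speaker selection.

Defaults (coverage .6; retrace/repetition .06; semantic/phonemic
paraphasia .03; dialect .08; 4 fillers; 4–9 tokens per utterance) sketch a
mildly disfluent narrative sample. `generate_corpus` draws per-transcript
coverage from Uniform(.30, .90) to emulate the ability spread of a mixed
clinical/control sample — a single fixed coverage would understate the
between-sample variance every ICC rests on. `simulate_manual_scorer`
flips credited cells to 0 with a configurable omission rate, the error
profile observed for trained hand scorers (items produced but missed).

What the generator does **not** model: real syntax or discourse structure,
severity strata, unintelligible stretches, transcription errors
(e.g. a revision miscoded as a repetition), or vocabulary outside its
tables. A green oracle-equivalence test therefore establishes that the
engine implements the stated scoring rules exactly on coded transcripts —
not that it survives arbitrary real-world CHAT, and not that the packaged
checklists match published norms.

## Numerical and design choices

- Utterance/token indices 0-based; gem ranges half-open; speaker codes and
  task ids case-insensitive; all matching lowercase.
- Unsupported inline codes are preserved verbatim and flagged, never
  dropped; unknown dependent tiers pass through opaquely.
- A `%mor` tier that fails to align with its utterance's parseable tokens
  is discarded with a warning on that utterance (fallback takes over),
  not a fatal error.
- Corpus child seeds derive from the master seed via the NumPy generator
  and stay below 2^31.
- Batch scoring processes files in sorted name order; unparseable files
  are logged and skipped, never fatal; zero matches is an error.

## Limitations

Scores depend on the checklist file used (hence the hash stamping); the
packaged lists are stand-ins. The fallback analyzer is intentionally
bounded — for research-grade morphology, supply transcripts with `%mor`
tiers. Normative percentile comparison is out of scope: no norm tables
ship with the package.
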