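"""Reading and writing the CHAT transcript subset the scoring method needs.

CHAT (the TalkBank transcription convention) marks speakers on main tiers
(``*PAR:``), analyses on dependent tiers (``%mor:``) and metadata on header
lines (``@...``).  This module supports exactly the constructs the core-lexicon
pipeline touches:

* headers, gem markers (``@G``, ``@Bg``/``@Eg``) delimiting task segments;
* main-tier tokens with target replacements ``[: word]`` / ``[:: word]``,
  error class codes ``[* ...]``, repetition ``[/]`` and retrace ``[//]``
  scoping (single token or ``<...>`` group), ``&``-prefixed fillers and the
  unintelligible markers ``xxx``/``yyy``/``www``;
* ``%mor`` morphology tiers (part of speech, lemma, inflection tags, clitics),
  aligned to the tokens CHAT morphology would parse.

Anything else on a main tier is preserved verbatim as an unknown code and
flagged, never silently dropped; unknown dependent tiers pass through opaquely.
Utterance and token indices are 0-based and gem ranges are half-open.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace

from .errors import ChatParseError, TaskNotFoundError
from .tasks import resolve_task


class ReplacementStyle(str, enum.Enum):
    NONE = "none"
    SINGLE_COLON = "single_colon"
    DOUBLE_COLON = "double_colon"


class ScopeRole(str, enum.Enum):
    PLAIN = "plain"
    RETRACE_MATERIAL = "retrace_material"
    REPETITION_MATERIAL = "repetition_material"


@dataclass
class Token:
    """One surface token of a main tier with its inline CHAT codes."""

    surface: str
    replacement_target: str | None = None
    replacement_style: ReplacementStyle = ReplacementStyle.NONE
    error_codes: list[str] = field(default_factory=list)
    scope_role: ScopeRole = ScopeRole.PLAIN
    is_filler: bool = False
    is_unintelligible: bool = False
    # Tokens sharing a scope_group were bracketed together (<...> [//]);
    # needed only to regenerate the original grouping on write.
    scope_group: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        has_target = self.replacement_target is not None
        if has_target != (self.replacement_style is not ReplacementStyle.NONE):
            raise ValueError("replacement_target and replacement_style disagree")
        if not self.is_filler and not self.surface:
            raise ValueError("non-filler token with empty surface")

    @property
    def is_scoreable(self) -> bool:
        """True when CHAT morphology would parse this token (pre-reformat)."""
        return (not self.is_filler and not self.is_unintelligible
                and self.scope_role is ScopeRole.PLAIN)


@dataclass
class MorWord:
    """One ``%mor`` tier entry: lemma, POS, inflection tags, clitic parts."""

    lemma: str
    pos: str = "x"
    inflection_tags: list[str] = field(default_factory=list)
    clitic_parts: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.lemma:
            raise ValueError("MorWord with empty lemma")

    def lemmas(self) -> list[str]:
        """All lemmas this entry contributes (main form plus clitics)."""
        return [self.lemma] + [lem for lem, _ in self.clitic_parts]


@dataclass
class Utterance:
    speaker: str
    tokens: list[Token]
    mor: list[MorWord] | None = None
    terminator: str = "."
    unknown_codes: list[str] = field(default_factory=list)
    raw_line: str = field(default="", compare=False)
    warnings: list[str] = field(default_factory=list, compare=False)
    extra_tiers: dict[str, str] = field(default_factory=dict)

    def scoreable_tokens(self) -> list[Token]:
        return [t for t in self.tokens if t.is_scoreable]


@dataclass
class Gem:
    """A task segment: ``[start, end)`` over utterance indices."""

    label: str
    start: int
    end: int
    style: str = "G"  # "G" (lazy gem) or "BgEg" (bracketed gem)

    @property
    def task_id(self) -> str | None:
        return resolve_task(self.label)


@dataclass
class Transcript:
    headers: list[tuple[str, str]] = field(default_factory=list)
    utterances: list[Utterance] = field(default_factory=list)
    gems: list[Gem] = field(default_factory=list)

    @property
    def metadata(self) -> dict[str, str]:
        return dict(self.headers)

    def speakers(self) -> list[str]:
        seen: dict[str, None] = {}
        for u in self.utterances:
            seen.setdefault(u.speaker.upper())
        return list(seen)


# ---------------------------------------------------------------------------
# Parsing

_ELEM_RE = re.compile(r"\[[^\]]*\]|<|>|[^\s<>\[\]]+")
_TERMINATORS = {".", "!", "?"}
_UNINTELLIGIBLE = {"xxx", "yyy", "www"}


def _parse_main_tier(speaker: str, text: str, line_number: int) -> Utterance:
    tokens: list[Token] = []
    unknown: list[str] = []
    terminator = ""
    group_start: int | None = None
    pending_group: list[int] | None = None
    next_gid = 0

    for el in _ELEM_RE.findall(text):
        if el == "<":
            if group_start is not None:
                raise ChatParseError("nested '<' scope groups are unsupported",
                                     line_number)
            group_start = len(tokens)
            pending_group = None
        elif el == ">":
            if group_start is None:
                raise ChatParseError("unbalanced '>' without matching '<'",
                                     line_number)
            pending_group = list(range(group_start, len(tokens)))
            group_start = None
        elif el.startswith("["):
            inner = el[1:-1].strip()
            scope = pending_group if pending_group else (
                [len(tokens) - 1] if tokens else [])
            if inner in ("/", "//"):
                if not scope:
                    raise ChatParseError(f"scope marker {el} has no material",
                                         line_number)
                role = (ScopeRole.REPETITION_MATERIAL if inner == "/"
                        else ScopeRole.RETRACE_MATERIAL)
                gid = next_gid
                next_gid += 1
                for i in scope:
                    tokens[i].scope_role = role
                    tokens[i].scope_group = gid
                pending_group = None
            elif inner.startswith("::"):
                _set_replacement(tokens, scope, inner[2:].strip(),
                                 ReplacementStyle.DOUBLE_COLON, el, line_number)
                pending_group = None
            elif inner.startswith(":"):
                _set_replacement(tokens, scope, inner[1:].strip(),
                                 ReplacementStyle.SINGLE_COLON, el, line_number)
                pending_group = None
            elif inner.startswith("*"):
                if not scope:
                    raise ChatParseError(f"error code {el} has no target token",
                                         line_number)
                tokens[scope[-1]].error_codes.append(inner[1:].strip())
                pending_group = None
            else:
                # Unsupported code: preserved verbatim, flagged, not dropped.
                unknown.append(el)
        else:
            if el in _TERMINATORS or (len(el) > 1 and set(el) <= set("+/.!?")):
                terminator = el
                continue
            if el == ",":
                continue
            tokens.append(Token(
                surface=el,
                is_filler=el.startswith("&"),
                is_unintelligible=el.lower() in _UNINTELLIGIBLE,
            ))
            if group_start is None:
                pending_group = None

    if group_start is not None:
        raise ChatParseError("unbalanced '<' without matching '>'", line_number)

    return Utterance(speaker=speaker, tokens=tokens,
                     terminator=terminator or ".",
                     unknown_codes=unknown,
                     raw_line=f"*{speaker}:\t{text}")


def _set_replacement(tokens: list[Token], scope: list[int], target: str,
                     style: ReplacementStyle, code: str,
                     line_number: int) -> None:
    if not scope or not target:
        raise ChatParseError(f"replacement code [{code}] has no target token",
                             line_number)
    tok = tokens[scope[-1]]
    tok.replacement_target = target
    tok.replacement_style = style


_MOR_PART_RE = re.compile(r"^([\w:+#]+)\|(.+)$")
_MOR_TAG_RE = re.compile(r"[-&]([\w:]+)")


def _parse_mor_part(part: str) -> tuple[str, str, list[str]]:
    """Return (pos, lemma, tags) for one pos|lemma-TAG&TAG unit."""
    m = _MOR_PART_RE.match(part)
    if m is None:
        return "x", part.lower(), []
    pos, rest = m.group(1), m.group(2)
    body = re.match(r"^([^-&]+)", rest)
    lemma = (body.group(1) if body else rest).lower()
    tags = _MOR_TAG_RE.findall(rest[len(lemma):] if body else "")
    return pos, lemma, tags


def parse_mor_tier(text: str) -> list[MorWord]:
    """Parse a ``%mor`` tier body into :class:`MorWord` entries.

    Punctuation entries are dropped; ``~``-joined clitic clusters become one
    entry with ``clitic_parts`` (e.g. ``cop|be&3S~neg|not`` for "isn't").
    """
    out: list[MorWord] = []
    for item in text.split():
        if set(item) <= set(".!?+/"):
            continue
        parts = item.split("~")
        pos, lemma, tags = _parse_mor_part(parts[0])
        clitics = []
        for clit in parts[1:]:
            cpos, clemma, _ = _parse_mor_part(clit)
            clitics.append((clemma, cpos))
        out.append(MorWord(lemma=lemma, pos=pos, inflection_tags=tags,
                           clitic_parts=clitics))
    return out


def _logical_lines(text: str) -> list[tuple[int, str]]:
    """Join CHAT continuation lines (leading whitespace) to their tier line."""
    out: list[tuple[int, str]] = []
    for i, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line[0] in " \t" and out:
            num, prev = out[-1]
            out[-1] = (num, prev + " " + line.strip())
        else:
            out.append((i, line.rstrip()))
    return out


def parse_chat(text: str) -> Transcript:
    """Parse CHAT file content into a :class:`Transcript`.

    Raises :class:`ChatParseError` (with a line number) for lines that are not
    header, main-tier or dependent-tier lines, and for structurally broken
    scope brackets.  A ``%mor`` tier whose entry count does not match the
    parseable tokens of its utterance is discarded with a warning recorded on
    the utterance.
    """
    t = Transcript()
    open_g: Gem | None = None
    open_bg: list[Gem] = []

    for line_number, line in _logical_lines(text):
        marker = line[0]
        if marker == "@":
            key, _, value = line[1:].partition(":")
            key, value = key.strip(), value.strip()
            pos = len(t.utterances)
            if key == "G":
                if open_g is not None:
                    open_g.end = pos
                open_g = Gem(label=value, start=pos, end=pos, style="G")
                t.gems.append(open_g)
            elif key == "Bg":
                gem = Gem(label=value, start=pos, end=pos, style="BgEg")
                open_bg.append(gem)
                t.gems.append(gem)
            elif key == "Eg":
                for gem in reversed(open_bg):
                    if not value or gem.label == value:
                        gem.end = pos
                        open_bg.remove(gem)
                        break
            elif key in ("Begin", "End"):
                pass
            else:
                t.headers.append((key, value))
        elif marker == "*":
            speaker, sep, body = line[1:].partition(":")
            if not sep:
                raise ChatParseError("main tier missing ':' after speaker code",
                                     line_number)
            t.utterances.append(
                _parse_main_tier(speaker.strip(), body.strip(), line_number))
        elif marker == "%":
            if not t.utterances:
                raise ChatParseError("dependent tier before any main tier",
                                     line_number)
            tier, sep, body = line[1:].partition(":")
            if not sep:
                raise ChatParseError("dependent tier missing ':'", line_number)
            tier, body = tier.strip(), body.strip()
            utt = t.utterances[-1]
            if tier == "mor":
                mor = parse_mor_tier(body)
                expected = len(utt.scoreable_tokens())
                if len(mor) == expected:
                    utt.mor = mor
                else:
                    utt.warnings.append(
                        f"%mor alignment failure: {len(mor)} entries for "
                        f"{expected} parseable tokens; tier ignored")
            else:
                utt.extra_tiers[tier] = body
        else:
            raise ChatParseError(
                f"unsupported line start {marker!r} (expected *, % or @)",
                line_number)

    pos = len(t.utterances)
    if open_g is not None:
        open_g.end = pos
    for gem in open_bg:
        gem.end = pos
    t.gems = [g for g in t.gems if g.end > g.start]
    return t


def read_chat(path) -> Transcript:
    with open(path, encoding="utf-8") as fh:
        return parse_chat(fh.read())


# ---------------------------------------------------------------------------
# Writing

def _format_token(tok: Token) -> str:
    parts = [tok.surface]
    if tok.replacement_style is ReplacementStyle.SINGLE_COLON:
        parts.append(f"[: {tok.replacement_target}]")
    elif tok.replacement_style is ReplacementStyle.DOUBLE_COLON:
        parts.append(f"[:: {tok.replacement_target}]")
    for code in tok.error_codes:
        parts.append(f"[* {code}]")
    return " ".join(parts)


_ROLE_MARKER = {ScopeRole.REPETITION_MATERIAL: "[/]",
                ScopeRole.RETRACE_MATERIAL: "[//]"}


def _format_main_tier(utt: Utterance) -> str:
    chunks: list[str] = []
    i = 0
    toks = utt.tokens
    while i < len(toks):
        tok = toks[i]
        if tok.scope_role is ScopeRole.PLAIN:
            chunks.append(_format_token(tok))
            i += 1
            continue
        j = i
        while (j + 1 < len(toks)
               and toks[j + 1].scope_role is tok.scope_role
               and toks[j + 1].scope_group == tok.scope_group
               and tok.scope_group is not None):
            j += 1
        group = " ".join(_format_token(toks[k]) for k in range(i, j + 1))
        if j > i:
            group = f"<{group}>"
        chunks.append(f"{group} {_ROLE_MARKER[tok.scope_role]}")
        i = j + 1
    chunks.extend(utt.unknown_codes)
    chunks.append(utt.terminator)
    return f"*{utt.speaker}:\t" + " ".join(chunks)


def _format_mor_word(mw: MorWord) -> str:
    def one(pos: str, lemma: str, tags: list[str]) -> str:
        return pos + "|" + lemma + "".join("-" + t for t in tags)

    s = one(mw.pos, mw.lemma, mw.inflection_tags)
    for clemma, cpos in mw.clitic_parts:
        s += "~" + one(cpos, clemma, [])
    return s


def write_chat(t: Transcript) -> str:
    """Serialize a transcript; the output re-parses to an equal Transcript."""
    lines = ["@Begin"]
    for key, value in t.headers:
        lines.append(f"@{key}:\t{value}" if value else f"@{key}")
    starts: dict[int, list[Gem]] = {}
    ends: dict[int, list[Gem]] = {}
    for gem in t.gems:
        starts.setdefault(gem.start, []).append(gem)
        if gem.style == "BgEg":
            ends.setdefault(gem.end, []).append(gem)
    for i, utt in enumerate(t.utterances):
        for gem in ends.get(i, []):
            lines.append(f"@Eg:\t{gem.label}")
        for gem in starts.get(i, []):
            lines.append(f"@{'G' if gem.style == 'G' else 'Bg'}:\t{gem.label}")
        lines.append(_format_main_tier(utt))
        if utt.mor is not None:
            body = " ".join(_format_mor_word(mw) for mw in utt.mor)
            lines.append(f"%mor:\t{body} {utt.terminator}".rstrip())
        for tier, body in utt.extra_tiers.items():
            lines.append(f"%{tier}:\t{body}")
    n = len(t.utterances)
    for gem in ends.get(n, []):
        lines.append(f"@Eg:\t{gem.label}")
    lines.append("@End")
    return "\n".join(lines) + "\n"


def write_chat_file(t: Transcript, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_chat(t))


# ---------------------------------------------------------------------------
# Selection

def select_speaker(t: Transcript, code: str) -> list[Utterance]:
    """All utterances of one speaker (case-insensitive), in order."""
    code = code.strip().upper()
    return [u for u in t.utterances if u.speaker.strip().upper() == code]


def extract_task_segment(t: Transcript, task_id: str) -> Transcript:
    """The sub-transcript between a task's gem markers; metadata preserved."""
    wanted = resolve_task(task_id)
    for gem in t.gems:
        if gem.task_id == wanted and wanted is not None:
            match = gem
            break
        if gem.label.strip().lower() == task_id.strip().lower():
            match = gem
            break
    else:
        labels = [g.label for g in t.gems] or ["<none>"]
        raise TaskNotFoundError(
            f"task {task_id!r} absent; gems found: {', '.join(labels)}")
    sub = Transcript(headers=list(t.headers),
                     utterances=t.utterances[match.start:match.end],
                     gems=[replace(match, start=0,
                                   end=match.end - match.start)])
    return sub
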