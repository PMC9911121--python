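"""Parser/writer behavior for the supported CHAT subset."""

import pytest

from corelex import (ChatParseError, TaskNotFoundError, extract_task_segment,
                     parse_chat, select_speaker, write_chat)
from corelex.chat_io import ReplacementStyle, ScopeRole

from conftest import EXAMPLE_UTTERANCE, make_transcript


class TestParse:
    def test_example_utterance_with_mor(self, example_transcript):
        t = example_transcript
        assert len(t.utterances) == 1
        utt = t.utterances[0]
        assert utt.speaker == "PAR"
        assert len(utt.scoreable_tokens()) == 5
        assert [m.lemma for m in utt.mor] == ["knock", "it", "off", "the",
                                              "table"]

    def test_empty_input(self):
        t = parse_chat("")
        assert t.utterances == [] and t.gems == []

    def test_double_colon_replacement(self):
        t = parse_chat("*PAR:\tbrother [:: sister] went .\n")
        tok = t.utterances[0].tokens[0]
        assert tok.surface == "brother"
        assert tok.replacement_target == "sister"
        assert tok.replacement_style is ReplacementStyle.DOUBLE_COLON

    def test_error_codes_attach_to_replaced_token(self):
        t = parse_chat("*PAR:\tbrother [: sister] [* s:r] ran .\n")
        tok = t.utterances[0].tokens[0]
        assert tok.replacement_style is ReplacementStyle.SINGLE_COLON
        assert tok.error_codes == ["s:r"]

    def test_scope_groups(self):
        t = parse_chat("*PAR:\t<the boy> [//] the girl ran .\n"
                       "*PAR:\tthe [/] the dog .\n")
        roles = [tok.scope_role for tok in t.utterances[0].tokens]
        assert roles == [ScopeRole.RETRACE_MATERIAL,
                         ScopeRole.RETRACE_MATERIAL,
                         ScopeRole.PLAIN, ScopeRole.PLAIN, ScopeRole.PLAIN]
        rep = t.utterances[1].tokens
        assert rep[0].scope_role is ScopeRole.REPETITION_MATERIAL
        assert rep[1].scope_role is ScopeRole.PLAIN

    def test_fillers_and_unintelligible(self):
        t = parse_chat("*PAR:\t&-um the xxx dog .\n")
        toks = t.utterances[0].tokens
        assert toks[0].is_filler and toks[2].is_unintelligible
        assert [tok.surface for tok in t.utterances[0].scoreable_tokens()] \
            == ["the", "dog"]

    def test_unknown_codes_preserved_not_dropped(self):
        t = parse_chat("*PAR:\tthe dog ran [+ gram] .\n")
        assert t.utterances[0].unknown_codes == ["[+ gram]"]

    @pytest.mark.parametrize("bad", [
        "hello there\n",                       # no tier prefix
        "*PAR:\t<the boy the girl .\n",        # unbalanced <
        "*PAR:\tthe boy> ran .\n",             # unbalanced >
    ])
    def test_malformed_lines_raise_with_line_number(self, bad):
        with pytest.raises(ChatParseError) as exc:
            parse_chat(bad)
        assert "line 1" in str(exc.value)

    def test_mor_misalignment_recorded_not_fatal(self):
        t = parse_chat("*PAR:\tthe dog ran .\n%mor:\tdet:art|the n|dog .\n")
        utt = t.utterances[0]
        assert utt.mor is None
        assert any("alignment" in w for w in utt.warnings)

    def test_mor_skips_repetition_material(self):
        # Repetition-scoped words have no %mor entry.
        t = parse_chat("*PAR:\tthe [/] the dog ran .\n"
                       "%mor:\tdet:art|the n|dog v|run&PAST .\n")
        assert [m.lemma for m in t.utterances[0].mor] == ["the", "dog", "run"]

    def test_clitic_mor_entry(self):
        t = parse_chat("*PAR:\tisn't it .\n"
                       "%mor:\tcop|be&3S~neg|not pro:per|it .\n")
        mw = t.utterances[0].mor[0]
        assert mw.lemma == "be" and mw.clitic_parts == [("not", "neg")]

    def test_continuation_lines_joined(self):
        t = parse_chat("*PAR:\tthe dog\n\tran away .\n")
        assert [tok.surface for tok in t.utterances[0].tokens] \
            == ["the", "dog", "ran", "away"]


class TestWrite:
    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("task", ["BrokenWindow", "Cinderella"])
    def test_round_trip_law(self, seed, task):
        # parse . write . parse == parse on generated fixtures
        t, _ = make_transcript(seed=seed, task=task)
        once = parse_chat(write_chat(t))
        twice = parse_chat(write_chat(once))
        assert once == twice

    def test_double_colon_emitted_literally(self):
        t = parse_chat("*PAR:\tbrother [:: sister] went .\n")
        assert "[:: sister]" in write_chat(t)

    def test_empty_transcript_is_header_only(self):
        out = write_chat(parse_chat(""))
        assert out.splitlines() == ["@Begin", "@End"]

    def test_token_counts_preserved_without_mor(self):
        with_mor = parse_chat(EXAMPLE_UTTERANCE)
        without = parse_chat(EXAMPLE_UTTERANCE.splitlines()[0] + "\n")
        assert [len(u.tokens) for u in with_mor.utterances] \
            == [len(u.tokens) for u in without.utterances]


class TestSelection:
    TWO_SPEAKERS = ("*INV:\ttell me the story .\n"
                    "*PAR:\tthe boy kicked .\n"
                    "*INV:\tgood .\n"
                    "*PAR:\tthe window broke .\n")

    def test_select_participant_only(self):
        t = parse_chat(self.TWO_SPEAKERS)
        par = select_speaker(t, "par")
        assert [u.speaker for u in par] == ["PAR", "PAR"]
        assert par[0].tokens[1].surface == "boy"

    def test_absent_speaker_empty(self):
        assert select_speaker(parse_chat(self.TWO_SPEAKERS), "CHI") == []

    def test_speaker_partition(self):
        t = parse_chat(self.TWO_SPEAKERS)
        merged = []
        for code in t.speakers():
            merged.extend(select_speaker(t, code))
        assert sorted(map(id, merged)) == sorted(map(id, t.utterances))

    def test_full_selection_is_identity(self):
        t = parse_chat("*PAR:\tone .\n*PAR:\ttwo .\n")
        assert select_speaker(t, "PAR") == t.utterances


class TestGems:
    FIVE_GEMS = "".join(
        f"@G:\t{label}\n*PAR:\t{word} .\n"
        for label, word in [("Window", "window"), ("Cat", "cat"),
                            ("Cinderella", "cinderella"),
                            ("Umbrella", "umbrella"), ("Sandwich", "bread")])

    def test_extract_one_task(self):
        t = parse_chat(self.FIVE_GEMS)
        sub = extract_task_segment(t, "CatRescue")
        assert len(sub.utterances) == 1
        assert sub.utterances[0].tokens[0].surface == "cat"

    def test_single_task_transcript_identity(self):
        t = parse_chat("@G:\tWindow\n*PAR:\tthe window broke .\n")
        sub = extract_task_segment(t, "BrokenWindow")
        assert sub.utterances == t.utterances

    def test_missing_task_lists_available_gems(self):
        t = parse_chat("@G:\tWindow\n*PAR:\tx .\n")
        with pytest.raises(TaskNotFoundError) as exc:
            extract_task_segment(t, "Cinderella")
        assert "Window" in str(exc.value)

    def test_bg_eg_brackets(self):
        t = parse_chat("@Bg:\tWindow\n*PAR:\tone .\n@Eg:\tWindow\n"
                       "*PAR:\ttwo .\n")
        sub = extract_task_segment(t, "BrokenWindow")
        assert len(sub.utterances) == 1
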