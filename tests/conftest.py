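import pytest

from corelex import builtin_lexicon, parse_chat
from corelex.synthetic import GenerationConfig, generate_transcript

EXAMPLE_UTTERANCE = (
    "*PAR:\tknocks it off the table .\n"
    "%mor:\tv|knock-3S pro:per|it prep|off det:art|the n|table .\n"
)


@pytest.fixture
def example_transcript():
    """The worked single-utterance example with its morphology tier."""
    return parse_chat(EXAMPLE_UTTERANCE)


@pytest.fixture
def cat_lexicon():
    return builtin_lexicon("CatRescue")


@pytest.fixture
def window_lexicon():
    return builtin_lexicon("BrokenWindow")


def make_transcript(seed=0, task="BrokenWindow", **overrides):
    """Generated fixture transcript plus its ground truth."""
    cfg = GenerationConfig(task_id=task, seed=seed, **overrides)
    return generate_transcript(cfg, builtin_lexicon(task),
                               sample_id=f"s{seed}")
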