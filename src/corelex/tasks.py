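"""Registry of the five structured discourse tasks and their gem-label aliases.

AphasiaBank sessions contain several elicitation tasks in one transcript,
delimited by gem markers whose spelling varies across contributors ("Window",
"Broken_Window", ...).  The registry maps those spellings onto canonical task
ids and is user-extensible at run time via :func:`register_alias`.
"""

from __future__ import annotations

CANONICAL_TASKS = (
    "BrokenWindow",
    "CatRescue",
    "Cinderella",
    "RefusedUmbrella",
    "Sandwich",
)

_ALIASES: dict[str, str] = {}


def _norm(label: str) -> str:
    return label.strip().lower().replace("_", "").replace("-", "").replace(" ", "")


def register_alias(alias: str, canonical: str) -> None:
    """Register an extra gem spelling for one of the known tasks."""
    if canonical not in CANONICAL_TASKS:
        raise ValueError(f"unknown canonical task {canonical!r}; "
                         f"expected one of {CANONICAL_TASKS}")
    _ALIASES[_norm(alias)] = canonical


def resolve_task(label: str) -> str | None:
    """Map a gem label or user-supplied task name to a canonical task id.

    Returns ``None`` when the label is not a registered spelling; callers may
    still match raw gem labels verbatim.
    """
    return _ALIASES.get(_norm(label))


for _canon in CANONICAL_TASKS:
    register_alias(_canon, _canon)

# Common AphasiaBank gem spellings; best-effort, extensible by users.
register_alias("Window", "BrokenWindow")
register_alias("Broken Window", "BrokenWindow")
register_alias("Cat", "CatRescue")
register_alias("Cat Rescue", "CatRescue")
register_alias("Umbrella", "RefusedUmbrella")
register_alias("Refused Umbrella", "RefusedUmbrella")
register_alias("Cinderella Story", "Cinderella")
register_alias("Sandwich Picnic", "Sandwich")
register_alias("Sandwich Other", "Sandwich")
register_alias("PeanutButter", "Sandwich")
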