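"""Experimental condition taxonomy.

A session is one tDCS priming visit (anodal, cathodal or sham).  Within a
session the participant performs two tasks -- movement *observation* and
movement *imagery* -- and each task has three movement types: *biological*
(a hand pincer movement), *nonbiological* (two spheres moving analogously)
and *control* (a white-noise video for observation; imagined white noise for
imagery).  The control movement is the denominator of the ERD ratio and never
appears as a dependent-variable level.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError

SESSIONS = ("anodal", "cathodal", "sham")
TASKS = ("observation", "imagery")
MOVEMENTS = ("biological", "nonbiological", "control")

#: movement levels that enter the statistical design (control is the baseline)
ACTIVE_MOVEMENTS = ("biological", "nonbiological")


@dataclass(frozen=True)
class ConditionKey:
    """Identifies one experimental condition within a recording session."""

    session: str
    task: str
    movement: str

    def __post_init__(self) -> None:
        if self.session not in SESSIONS:
            raise ParameterError(f"unknown session {self.session!r}; expected one of {SESSIONS}")
        if self.task not in TASKS:
            raise ParameterError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.movement not in MOVEMENTS:
            raise ParameterError(
                f"unknown movement {self.movement!r}; expected one of {MOVEMENTS}"
            )

    @property
    def is_control(self) -> bool:
        return self.movement == "control"

    def control_key(self) -> "ConditionKey":
        """The matching control condition (same session and task)."""
        return ConditionKey(self.session, self.task, "control")
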