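"""Channel-role declarations for EGI-style sensor nets.

Every downstream stage -- artifact rejection (which needs the periocular and
canthus sensors), average re-referencing (scalp channels only) and the ERD
electrode units (C3, C4, Cz and the two six-sensor surround rings) -- consults
a :class:`ChannelLayout` rather than hard-coded sensor numbers.

Sensor numbering is 1-based, matching EGI convention.  On the 128-channel
geodesic net, C3 is sensor 36 and C4 is sensor 104; the surround rings are
sensors {29, 30, 35, 37, 41, 42} and {87, 93, 103, 105, 110, 111}.  The vertex
itself is the physical reference of that net and carries no sensor number, so
the default layout maps the Cz role to the vertex-adjacent sensor 55; all role
assignments are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple

import yaml

from .errors import LayoutError

ROLE_C3 = "C3"
ROLE_C4 = "C4"
ROLE_CZ = "Cz"
ROLE_SURROUND_C3 = "surroundC3-member"
ROLE_SURROUND_C4 = "surroundC4-member"
ROLE_ABOVE_LEFT = "periocular-above-left"
ROLE_BELOW_LEFT = "periocular-below-left"
ROLE_ABOVE_RIGHT = "periocular-above-right"
ROLE_BELOW_RIGHT = "periocular-below-right"
ROLE_CANTHUS_LEFT = "canthus-left"
ROLE_CANTHUS_RIGHT = "canthus-right"
ROLE_OTHER = "other"

_SINGLETON_ROLES = (
    ROLE_C3,
    ROLE_C4,
    ROLE_CZ,
    ROLE_ABOVE_LEFT,
    ROLE_BELOW_LEFT,
    ROLE_ABOVE_RIGHT,
    ROLE_BELOW_RIGHT,
    ROLE_CANTHUS_LEFT,
    ROLE_CANTHUS_RIGHT,
)

_EOG_ROLES = (
    ROLE_ABOVE_LEFT,
    ROLE_BELOW_LEFT,
    ROLE_ABOVE_RIGHT,
    ROLE_BELOW_RIGHT,
    ROLE_CANTHUS_LEFT,
    ROLE_CANTHUS_RIGHT,
)

_ALL_ROLES = set(_SINGLETON_ROLES) | {ROLE_SURROUND_C3, ROLE_SURROUND_C4, ROLE_OTHER}

#: the five electrode units the analysis reports
UNITS = ("C3", "C4", "Cz", "surroundC3", "surroundC4")

DEFAULT_SURROUND_C3 = (29, 30, 35, 37, 41, 42)
DEFAULT_SURROUND_C4 = (87, 93, 103, 105, 110, 111)


@dataclass(frozen=True)
class ChannelLayout:
    """Mapping from sensor numbers to functional roles.

    Channels absent from ``role_map`` implicitly carry the role ``other``.
    """

    n_channels: int
    role_map: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise LayoutError("layout needs at least 2 channels")
        by_role: Dict[str, list] = {}
        for ch, role in self.role_map.items():
            if not (1 <= int(ch) <= self.n_channels):
                raise LayoutError(f"channel {ch} outside 1..{self.n_channels}")
            if role not in _ALL_ROLES:
                raise LayoutError(f"unknown role {role!r} for channel {ch}")
            by_role.setdefault(role, []).append(int(ch))
        for role in _SINGLETON_ROLES:
            n = len(by_role.get(role, []))
            if n != 1:
                raise LayoutError(f"role {role!r} must be assigned to exactly one channel, got {n}")
        s3 = set(by_role.get(ROLE_SURROUND_C3, []))
        s4 = set(by_role.get(ROLE_SURROUND_C4, []))
        if not s3 or not s4:
            raise LayoutError("both surround rings must have at least one member")
        if s3 & s4:
            raise LayoutError(f"surround rings overlap: {sorted(s3 & s4)}")
        central = {by_role[ROLE_C3][0], by_role[ROLE_C4][0], by_role[ROLE_CZ][0]}
        if (s3 | s4) & central:
            raise LayoutError("surround rings must exclude C3/C4/Cz")
        object.__setattr__(self, "_by_role", {k: tuple(sorted(v)) for k, v in by_role.items()})

    # -- single-channel accessors ------------------------------------------
    def _one(self, role: str) -> int:
        return self._by_role[role][0]

    @property
    def c3(self) -> int:
        return self._one(ROLE_C3)

    @property
    def c4(self) -> int:
        return self._one(ROLE_C4)

    @property
    def cz(self) -> int:
        return self._one(ROLE_CZ)

    @property
    def surround_c3(self) -> Tuple[int, ...]:
        return self._by_role[ROLE_SURROUND_C3]

    @property
    def surround_c4(self) -> Tuple[int, ...]:
        return self._by_role[ROLE_SURROUND_C4]

    @property
    def veog_pairs(self) -> Tuple[Tuple[int, int], Tuple[int, int]]:
        """(above, below) sensor pairs for the left and right eye."""
        return (
            (self._one(ROLE_ABOVE_LEFT), self._one(ROLE_BELOW_LEFT)),
            (self._one(ROLE_ABOVE_RIGHT), self._one(ROLE_BELOW_RIGHT)),
        )

    @property
    def heog_pair(self) -> Tuple[int, int]:
        """(left, right) outer-canthus sensor pair."""
        return (self._one(ROLE_CANTHUS_LEFT), self._one(ROLE_CANTHUS_RIGHT))

    @property
    def eog_channels(self) -> Tuple[int, ...]:
        return tuple(sorted(self._one(r) for r in _EOG_ROLES))

    @property
    def scalp_channels(self) -> Tuple[int, ...]:
        """All channels except the periocular/canthus set (average-reference pool)."""
        eog = set(self.eog_channels)
        return tuple(ch for ch in range(1, self.n_channels + 1) if ch not in eog)

    @property
    def unit_channels(self) -> Dict[str, Tuple[int, ...]]:
        """Member channels of each reported electrode unit."""
        return {
            "C3": (self.c3,),
            "C4": (self.c4,),
            "Cz": (self.cz,),
            "surroundC3": self.surround_c3,
            "surroundC4": self.surround_c4,
        }

    @property
    def analysis_channels(self) -> Tuple[int, ...]:
        out: list = []
        for chans in self.unit_channels.values():
            out.extend(chans)
        return tuple(sorted(set(out)))

    def role(self, channel: int) -> str:
        return self.role_map.get(channel, ROLE_OTHER)

    def cluster_role(self, channel: int) -> str:
        """Collapse the role to the ERD cluster it belongs to.

        Returns one of ``C3, C4, Cz, surroundC3, surroundC4, other, eog``.
        """
        r = self.role(channel)
        if r in (ROLE_C3, ROLE_C4, ROLE_CZ):
            return r
        if r == ROLE_SURROUND_C3:
            return "surroundC3"
        if r == ROLE_SURROUND_C4:
            return "surroundC4"
        if r in _EOG_ROLES:
            return "eog"
        return "other"

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "n_channels": self.n_channels,
            "roles": {int(ch): role for ch, role in sorted(self.role_map.items())},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ChannelLayout":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        try:
            return cls(int(doc["n_channels"]), {int(k): v for k, v in doc["roles"].items()})
        except (KeyError, TypeError) as exc:
            raise LayoutError(f"malformed layout file {path}: {exc}") from exc


def default_egi128_layout(
    c3: int = 36,
    c4: int = 104,
    cz: int = 55,
    surround_c3: Iterable[int] = DEFAULT_SURROUND_C3,
    surround_c4: Iterable[int] = DEFAULT_SURROUND_C4,
    periocular_above: Tuple[int, int] = (25, 8),
    periocular_below: Tuple[int, int] = (127, 126),
    canthi: Tuple[int, int] = (125, 128),
) -> ChannelLayout:
    """The 128-channel geodesic-net layout used throughout the package.

    Periocular/canthus assignments follow the conventional EGI-128 EOG sensor
    set; ``periocular_above``/``periocular_below`` are (left, right) pairs.
    """
    role_map: Dict[int, str] = {c3: ROLE_C3, c4: ROLE_C4, cz: ROLE_CZ}
    for ch in surround_c3:
        role_map[ch] = ROLE_SURROUND_C3
    for ch in surround_c4:
        role_map[ch] = ROLE_SURROUND_C4
    role_map[periocular_above[0]] = ROLE_ABOVE_LEFT
    role_map[periocular_below[0]] = ROLE_BELOW_LEFT
    role_map[periocular_above[1]] = ROLE_ABOVE_RIGHT
    role_map[periocular_below[1]] = ROLE_BELOW_RIGHT
    role_map[canthi[0]] = ROLE_CANTHUS_LEFT
    role_map[canthi[1]] = ROLE_CANTHUS_RIGHT
    if len(role_map) != 3 + len(tuple(surround_c3)) + len(tuple(surround_c4)) + 6:
        raise LayoutError("default layout roles must reference distinct channels")
    return ChannelLayout(128, role_map)


def minimal_layout() -> ChannelLayout:
    """Smallest layout carrying every role: 21 channels, ids 1..21.

    Used for reduced-size simulation studies where the full 128-sensor net
    would only add computation on channels no stage consumes.
    """
    role_map: Dict[int, str] = {1: ROLE_C3, 2: ROLE_C4, 3: ROLE_CZ}
    for ch in range(4, 10):
        role_map[ch] = ROLE_SURROUND_C3
    for ch in range(10, 16):
        role_map[ch] = ROLE_SURROUND_C4
    role_map.update(
        {
            16: ROLE_ABOVE_LEFT,
            17: ROLE_BELOW_LEFT,
            18: ROLE_ABOVE_RIGHT,
            19: ROLE_BELOW_RIGHT,
            20: ROLE_CANTHUS_LEFT,
            21: ROLE_CANTHUS_RIGHT,
        }
    )
    return ChannelLayout(21, role_map)
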