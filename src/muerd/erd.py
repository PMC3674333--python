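"""Control-normalized log power-ratio ERD index and electrode-unit tables.

The ERD index is ``ln(power_condition / power_control)``, where the control
is the same task's white-noise condition from the same subject, session and
channel.  Negative values mean desynchronization (ERD), positive values
synchronization (ERS).  Dividing by the control removes between-subject
variability in absolute Mu power, and the log transform undoes the lower
bounding of ratio data; the package uses the natural log throughout (recorded
in the table metadata; the choice of base rescales every value by a constant
and affects no test statistic).

The reported electrode units are C3, C4 and Cz (single sensors) and
surroundC3 / surroundC4, each the arithmetic mean of its six member sensors'
per-electrode log ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Tuple, Union

import numpy as np
import pandas as pd

from .conditions import ACTIVE_MOVEMENTS, TASKS
from .errors import DegenerateDataError, LayoutError, ParameterError, PairingError
from .layout import UNITS, ChannelLayout

ERD_COLUMNS = ("subject", "session", "task", "movement", "unit", "erd")


def erd_index(
    power_condition: Union[float, np.ndarray, pd.Series],
    power_control: Union[float, np.ndarray, pd.Series],
) -> Union[float, np.ndarray, pd.Series]:
    """ln(power_condition / power_control); elementwise for array input."""
    pc = np.asarray(power_condition, dtype=float)
    p0 = np.asarray(power_control, dtype=float)
    if np.any(pc <= 0) or np.any(p0 <= 0):
        raise ParameterError("ERD index requires strictly positive powers")
    out = np.log(pc) - np.log(p0)
    if isinstance(power_condition, pd.Series):
        return pd.Series(out, index=power_condition.index)
    if np.isscalar(power_condition) or out.ndim == 0:
        return float(out)
    return out


def unit_erd(per_channel: pd.Series, layout: ChannelLayout, unit: str) -> float:
    """Aggregate per-channel ERD values to one electrode unit.

    C3/C4/Cz return the single sensor's value; the surround units return the
    arithmetic mean over their member sensors.
    """
    if unit not in UNITS:
        raise ParameterError(f"unknown unit {unit!r}; expected one of {UNITS}")
    members = layout.unit_channels[unit]
    values = per_channel.to_dict() if isinstance(per_channel, pd.Series) else dict(per_channel)
    missing = [c for c in members if c not in values]
    if missing:
        raise LayoutError(f"unit {unit}: channels {missing} missing from ERD values")
    return float(np.mean([values[c] for c in members]))


@dataclass
class SessionPowers:
    """Condition-level mean band power for one subject x session.

    ``powers`` maps (task, movement) to a per-channel power Series;
    ``retained`` maps the same keys to retained-epoch counts.
    """

    subject: int
    session: str
    powers: Dict[Tuple[str, str], pd.Series]
    retained: Dict[Tuple[str, str], int]


def build_erd_table(
    session_results: Iterable[SessionPowers], layout: ChannelLayout
) -> pd.DataFrame:
    """Assemble the long-format ERD table: one row per subject x session x
    task x active movement x electrode unit.

    The full 21-subject design yields 21 x 3 x 2 x 2 x 5 = 1260 rows.
    Raises if a task's control condition is absent (nothing to normalize by).
    """
    rows = []
    for sp in session_results:
        for task in TASKS:
            if (task, "control") not in sp.powers:
                raise DegenerateDataError(
                    f"subject {sp.subject} session {sp.session}: control condition "
                    f"for task {task!r} is missing"
                )
            control = sp.powers[(task, "control")]
            for movement in ACTIVE_MOVEMENTS:
                if (task, movement) not in sp.powers:
                    raise DegenerateDataError(
                        f"subject {sp.subject} session {sp.session}: condition "
                        f"({task}, {movement}) is missing"
                    )
                power = sp.powers[(task, movement)]
                if not power.index.equals(control.index):
                    raise PairingError(
                        "condition and control powers cover different channels"
                    )
                lr = erd_index(power, control)
                for unit in UNITS:
                    rows.append(
                        {
                            "subject": sp.subject,
                            "session": sp.session,
                            "task": task,
                            "movement": movement,
                            "unit": unit,
                            "erd": unit_erd(lr, layout, unit),
                        }
                    )
    table = pd.DataFrame(rows, columns=list(ERD_COLUMNS))
    table.attrs["log_base"] = "e"
    return table


def write_erd_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_erd_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(ERD_COLUMNS) - set(table.columns)
    if missing:
        raise ParameterError(f"ERD table {path} missing columns {sorted(missing)}")
    table.attrs["log_base"] = "e"
    return table
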