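"""Stimulation-dosimetry arithmetic (session metadata only).

The stimulation itself is outside the analysis pipeline; this helper exists
because the protocol's current density -- 2 mA through a 35 cm^2 sponge
electrode, i.e. 0.057 mA/cm^2 -- is part of the session metadata the package
records.
"""

from .errors import ParameterError


def current_density(current_ma: float = 2.0, electrode_area_cm2: float = 35.0) -> float:
    """Current density in mA/cm^2 for a given current and electrode area."""
    if current_ma <= 0 or electrode_area_cm2 <= 0:
        raise ParameterError("current and electrode area must be positive")
    return current_ma / electrode_area_cm2
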