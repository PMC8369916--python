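"""Channel open probability from MTSEA potentiation.

MTSEA covalently modifies an engineered cysteine in the channel gate
(GluN2A-A650C) and locks modified channels open.  The degree of current
potentiation by MTSEA is therefore inversely related to the open probability
the channels had before modification:

    P_open = (gamma_MTSEA / gamma_CONTROL) * (1 / potentiation)

where gamma is the chord conductance before/after modification and
``potentiation`` is the ratio of steady current after MTSEA to that before.
The conductance ratio is not measurable in these recordings; it ships as a
configuration constant with a calibration helper that inverts the relation
on a reference construct with known P_open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "PotentiationPair",
    "ConductanceRatio",
    "DEFAULT_GAMMA",
    "potentiation_ratio",
    "popen_from_mtsea",
    "calibrate_gamma",
]

GAMMA_SANITY_BOUND = 1.5  # chord-conductance ratios far above 1 are unphysical


@dataclass(frozen=True)
class PotentiationPair:
    """Steady agonist-evoked amplitudes before and after modulator exposure."""

    i_before: float  # nA
    i_after: float  # nA
    cell_id: str = ""
    condition: str = "MTSEA"

    def __post_init__(self) -> None:
        if self.i_before <= 0 or self.i_after <= 0:
            raise ValueError("amplitudes must be strictly positive")


@dataclass(frozen=True)
class ConductanceRatio:
    """gamma_MTSEA / gamma_CONTROL with provenance of how it was obtained."""

    gamma_ratio: float
    source: str = "configured"  # "configured" | "calibrated"

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma_ratio <= GAMMA_SANITY_BOUND:
            raise ValueError(
                f"gamma_ratio {self.gamma_ratio} outside sanity bound (0, {GAMMA_SANITY_BOUND}]"
            )


# Default conductance ratio, calibrated on wild-type GluN1/GluN2A receptors
# (P_open 0.26 at an MTSEA potentiation of 3.26x): 0.26 * 3.26 = 0.8476.
DEFAULT_GAMMA = ConductanceRatio(0.8476, source="calibrated")


def potentiation_ratio(pair: PotentiationPair) -> float:
    """Fold potentiation i_after / i_before (multiply by 100 for percent)."""
    return pair.i_after / pair.i_before


def popen_from_mtsea(potentiation: float, gamma: ConductanceRatio) -> float:
    """Open probability gamma_ratio / potentiation, in (0, 1].

    Requires potentiation >= gamma_ratio; anything less would imply P > 1,
    which indicates a mismatched conductance ratio or an unpotentiated cell.
    """
    if potentiation <= 0:
        raise ValueError("potentiation must be positive")
    if potentiation < gamma.gamma_ratio:
        raise ValueError(
            f"potentiation ({potentiation:g}) below gamma_ratio ({gamma.gamma_ratio:g}) "
            "would give P_open > 1; check calibration"
        )
    return gamma.gamma_ratio / potentiation


def calibrate_gamma(p_reference: float, potentiation_reference: float) -> ConductanceRatio:
    """Invert the MTSEA relation on a reference construct with known P_open.

    gamma_ratio = P_ref * potentiation_ref; the round trip
    ``popen_from_mtsea(x, calibrate_gamma(p, x)) == p`` holds exactly.
    """
    if p_reference <= 0 or p_reference > 1:
        raise ValueError("reference open probability must lie in (0, 1]")
    if potentiation_reference <= 0:
        raise ValueError("reference potentiation must be positive")
    return ConductanceRatio(p_reference * potentiation_reference, source="calibrated")


def mean_potentiation(pairs: Sequence[PotentiationPair]) -> float:
    """Mean fold potentiation across cells."""
    if not pairs:
        raise ValueError("no potentiation pairs supplied")
    return sum(potentiation_ratio(p) for p in pairs) / len(pairs)
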