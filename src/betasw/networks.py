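"""Sensorimotor network definitions over Brodmann-area ROIs.

The analysis operates on four weighted networks per subject: a motor and a
sensory network in each hemisphere.  Nodes are Brodmann areas (BAs); the
motor network comprises BA 4, 6, 8, 9, 24 and 32, the sensory network
BA 1, 2, 3, 5, 7, 40 and 43.  ROI labels follow the ``BA<k>_<L|R>``
convention used by the delimited time-series files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

MOTOR_BAS: tuple[int, ...] = (4, 6, 8, 9, 24, 32)
SENSORY_BAS: tuple[int, ...] = (1, 2, 3, 5, 7, 40, 43)

#: All 13 Brodmann areas of the sensorimotor montage, ascending.
ALL_BAS: tuple[int, ...] = tuple(sorted(MOTOR_BAS + SENSORY_BAS))

HEMISPHERES: tuple[str, str] = ("left", "right")
_HEMI_SUFFIX = {"left": "L", "right": "R"}


def roi_label(ba: int, hemisphere: str) -> str:
    """Canonical ROI label, e.g. ``roi_label(4, "left") == "BA4_L"``."""
    return f"BA{ba}_{_HEMI_SUFFIX[hemisphere]}"


#: Default 26-ROI montage: 13 BAs x 2 hemispheres, left block first.
DEFAULT_ROI_LABELS: tuple[str, ...] = tuple(
    roi_label(ba, hemi) for hemi in HEMISPHERES for ba in ALL_BAS
)


@dataclass(frozen=True)
class Band:
    """A frequency band in Hz.  Default of interest: beta, 13-30 Hz."""

    low_hz: float = 13.0
    high_hz: float = 30.0

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(
                f"invalid band ({self.low_hz}, {self.high_hz}): need 0 < low < high"
            )


BETA = Band(13.0, 30.0)


@dataclass(frozen=True)
class NetworkDefinition:
    """One network: name ('motor'|'sensory'), hemisphere, and its BAs."""

    name: str
    hemisphere: str
    brodmann_areas: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.name not in ("motor", "sensory"):
            raise ValueError(f"unknown network name {self.name!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        if not self.brodmann_areas:
            bas = MOTOR_BAS if self.name == "motor" else SENSORY_BAS
            object.__setattr__(self, "brodmann_areas", bas)

    @property
    def roi_labels(self) -> tuple[str, ...]:
        return tuple(roi_label(ba, self.hemisphere) for ba in self.brodmann_areas)


DEFAULT_NETWORKS: tuple[NetworkDefinition, ...] = tuple(
    NetworkDefinition(name, hemi)
    for name in ("motor", "sensory")
    for hemi in HEMISPHERES
)
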