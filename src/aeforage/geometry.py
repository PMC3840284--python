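"""Chamber geometry and the interresponse-energy (IRE) statistic.

The simulated apparatus is a circular touch surface (default 22 cm
diameter) on which a subject pecks.  The energy expended between two
consecutive pecks is summarised by the interresponse energy

    IRE = IRD**2 / IRT**2,

where IRD is the straight-line distance (m) between the two peck
locations and IRT the elapsed time (s) between them.  This is the
kinetic-energy form E = M * D**2 / T**2 with the subject's body mass M
held at 1 kg: mass is approximately constant for a single subject across
an experiment, so IRE is energy per unit body mass, conventionally
reported in joules.

All coordinates are continuous planar meters with the origin at the
center of the response area; pecks are treated as points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidArgumentError

__all__ = [
    "PeckEvent",
    "ChamberGeometry",
    "EnergyQuantities",
    "energy_expenditure",
    "compute_ire",
    "min_ird_to_meet",
]


@dataclass(frozen=True, slots=True)
class PeckEvent:
    """One touch on the response surface.

    Attributes
    ----------
    x, y : float
        Planar position in meters, origin at the response-area center.
    t : float
        Simulated clock time in seconds (non-negative).
    """

    x: float
    y: float
    t: float

    def distance_to(self, other: "PeckEvent") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass(frozen=True, slots=True)
class ChamberGeometry:
    """Physical layout of the response surface and choice keys.

    Defaults follow a standard pigeon touch-panel arrangement: a 22-cm
    circular response area containing two 5-cm keys whose centers are
    10 cm apart.
    """

    response_area_diameter: float = 0.22
    key_diameter: float = 0.05
    key_center_separation: float = 0.10
    key_center_height_offset: float = 0.0  # informational only

    def __post_init__(self) -> None:
        if self.key_diameter >= self.response_area_diameter:
            raise InvalidArgumentError(
                "key_diameter must be smaller than response_area_diameter"
            )
        # Both keys (centered on the horizontal midline, symmetric about the
        # origin) must fit inside the response area circle.
        key_extent = self.key_center_separation / 2 + self.key_diameter / 2
        if key_extent > self.response_area_diameter / 2:
            raise InvalidArgumentError(
                "keys do not fit inside the response area: half-separation + "
                "key radius exceeds the response-area radius"
            )

    @property
    def radius(self) -> float:
        """Radius of the circular response area in meters."""
        return self.response_area_diameter / 2

    def contains(self, x: float, y: float, tol: float = 1e-12) -> bool:
        """True if (x, y) lies within the response-area circle."""
        return math.hypot(x, y) <= self.radius + tol


@dataclass(frozen=True, slots=True)
class EnergyQuantities:
    """IRD, IRT and the resulting IRE for one peck pair.

    ``mass`` defaults to 1.0 kg (the unit-mass convention), making ``ire``
    energy per unit body mass.
    """

    ird: float
    irt: float
    ire: float
    mass: float = 1.0

    def __post_init__(self) -> None:
        if self.irt <= 0:
            raise InvalidArgumentError("irt must be positive")
        if self.ird < 0:
            raise InvalidArgumentError("ird must be non-negative")
        expected = self.mass * self.ird**2 / self.irt**2
        if not math.isclose(self.ire, expected, rel_tol=1e-9, abs_tol=1e-15):
            raise InvalidArgumentError(
                f"inconsistent energy quantities: ire={self.ire}, but "
                f"mass*ird^2/irt^2={expected}"
            )


def energy_expenditure(mass: float, distance: float, time: float) -> float:
    """Energy expended moving ``distance`` meters in ``time`` seconds.

    Implements E = M * D**2 / T**2 (joules), the kinetic-energy-scale
    measure of behavioral energy expenditure.

    Parameters
    ----------
    mass : float
        Body mass M in kilograms, > 0.
    distance : float
        Distance moved D in meters, >= 0.
    time : float
        Elapsed time T in seconds, > 0.
    """
    if time <= 0:
        raise InvalidArgumentError(f"time must be positive, got {time}")
    if mass <= 0:
        raise InvalidArgumentError(f"mass must be positive, got {mass}")
    if distance < 0:
        raise InvalidArgumentError(f"distance must be non-negative, got {distance}")
    return mass * distance**2 / time**2


def compute_ire(first: PeckEvent, second: PeckEvent) -> EnergyQuantities:
    """Interresponse energy of a consecutive peck pair.

    IRD is the straight-line distance between the two peck locations and
    IRT the elapsed time between them; IRE = IRD**2 / IRT**2 under the
    unit-mass convention.

    Raises
    ------
    InvalidArgumentError
        If ``second`` does not occur strictly after ``first``.
    """
    irt = second.t - first.t
    if irt <= 0:
        raise InvalidArgumentError(
            f"second peck must occur strictly after the first "
            f"(t1={first.t}, t2={second.t})"
        )
    ird = first.distance_to(second)
    return EnergyQuantities(ird=ird, irt=irt, ire=ird**2 / irt**2)


def min_ird_to_meet(ae_requirement: float, irt: float) -> float:
    """Infimum interresponse distance meeting an AE requirement.

    For a fixed IRT, IRE exceeds the requirement ``a`` iff
    IRD > IRT * sqrt(a); the returned boundary value itself yields
    IRE == a, which does *not* reinforce (reinforcement is strict).

    Examples: a 0.25-J requirement needs IRD > 0.05 m at IRT = 0.1 s and
    IRD > 0.1 m at IRT = 0.2 s.
    """
    if ae_requirement < 0:
        raise InvalidArgumentError(
            f"ae_requirement must be non-negative, got {ae_requirement}"
        )
    if irt <= 0:
        raise InvalidArgumentError(f"irt must be positive, got {irt}")
    return irt * math.sqrt(ae_requirement)
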