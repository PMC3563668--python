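"""Differential interfacial tension algebra for cell aggregates.

Under the differential interfacial tension hypothesis (DITH) a tissue behaves
like a liquid whose surface tension arises from per-cell interfacial tensions.
Each interface of a cell carries an effective cortical tension — ``Gamma_cm``
along the cell–medium interface, ``Gamma_cc`` along each cortex of a cell–cell
contact — and adhering surfaces gain an adhesion energy ``J`` per unit area.
The net interfacial tensions are then

    gamma_cm = Gamma_cm
    gamma_cc = 2*Gamma_cc - J        (two cortices share one contact)

and the tissue surface tension (TST) of an aggregate in medium is

    sigma = gamma_cm - gamma_cc / 2 = Gamma_cm - Gamma_cc + J/2.

Mechanical equilibrium of the cell/cell/medium triple junction fixes the
contact angle theta through the Young balance

    gamma_cc = 2 * gamma_cm * cos(theta / 2).

Measuring sigma for a wild-type tissue, sigma for a uniform-cortex tissue
(where Gamma_cm = Gamma_cc, hence sigma = J/2) and the wild-type contact
angle therefore determines all three parameters; :func:`solve_tensions`
implements that inversion and :func:`decompose_tst` splits sigma into its
contractility and adhesion parts.

Angles are degrees at the API boundary and radians internally.  A parameter
set is *equilibrium* when 0 <= gamma_cc <= 2*gamma_cm; non-equilibrium sets
are flagged, never rejected, because fitted values may wander outside the
physical cone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "TensionSet",
    "InterfacialTensions",
    "AngleMeasurement",
    "NoEquilibriumError",
    "interfacial_from_tensions",
    "tst_from_tensions",
    "angle_from_tensions",
    "adhesion_from_angle",
    "solve_tensions",
    "decompose_tst",
]


class NoEquilibriumError(ValueError):
    """Raised when no triple-junction equilibrium exists for the inputs."""


@dataclass(frozen=True)
class TensionSet:
    """DITH parameters of one tissue/condition.

    Attributes
    ----------
    Gamma_cm : float
        Effective cortical tension of the cell–medium interface (mN/m).
    Gamma_cc : float
        Effective cortical tension per cortex of a cell–cell contact (mN/m).
    J : float
        Adhesion energy of the cell–cell contact (mN/m); J >= 0.
    """

    Gamma_cm: float
    Gamma_cc: float
    J: float

    def __post_init__(self) -> None:
        for name in ("Gamma_cm", "Gamma_cc", "J"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.J < 0:
            raise ValueError("adhesion energy J must be non-negative")

    @property
    def is_equilibrium(self) -> bool:
        """Whether 0 <= gamma_cc <= 2*gamma_cm, i.e. a contact angle exists."""
        gcc = 2.0 * self.Gamma_cc - self.J
        return 0.0 <= gcc <= 2.0 * self.Gamma_cm


@dataclass(frozen=True)
class InterfacialTensions:
    """Net interfacial tensions gamma_cm (cell–medium) and gamma_cc (cell–cell), mN/m."""

    gamma_cm: float
    gamma_cc: float

    @property
    def is_equilibrium(self) -> bool:
        return 0.0 <= self.gamma_cc <= 2.0 * self.gamma_cm


@dataclass(frozen=True)
class AngleMeasurement:
    """A contact-angle measurement at the cell/cell/medium triple junction."""

    theta: float  # degrees
    n: int = 1
    sem: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 180.0:
            raise ValueError("theta must lie in [0, 180] degrees")


def interfacial_from_tensions(t: TensionSet) -> InterfacialTensions:
    """Map cortical tensions and adhesion to net interfacial tensions.

    gamma_cm = Gamma_cm and gamma_cc = 2*Gamma_cc - J: the cell–cell
    interface carries two contractile cortices and gains -J from adhesion.
    A negative gamma_cc (adhesion beating contractility) is returned as-is;
    the ``is_equilibrium`` flag on the result marks it unphysical.
    """
    return InterfacialTensions(gamma_cm=t.Gamma_cm, gamma_cc=2.0 * t.Gamma_cc - t.J)


def tst_from_tensions(t: TensionSet) -> float:
    """Tissue surface tension sigma = Gamma_cm - Gamma_cc + J/2 (mN/m).

    When the cortex is uniform (Gamma_cm == Gamma_cc) the contractility
    difference cancels and sigma = J/2: surface tension is pure adhesion.
    """
    return t.Gamma_cm - t.Gamma_cc + 0.5 * t.J


def angle_from_tensions(g: InterfacialTensions) -> float:
    """Contact angle from the Young balance gamma_cc = 2*gamma_cm*cos(theta/2).

    Returns theta in degrees.  Raises :class:`NoEquilibriumError` when
    gamma_cc > 2*gamma_cm (tensions cannot balance, the cells separate)
    and ``ValueError`` when gamma_cm <= 0.
    """
    if g.gamma_cm <= 0:
        raise ValueError("gamma_cm must be positive to define a contact angle")
    ratio = g.gamma_cc / (2.0 * g.gamma_cm)
    if ratio > 1.0:
        raise NoEquilibriumError(
            f"gamma_cc={g.gamma_cc} exceeds 2*gamma_cm={2 * g.gamma_cm}: "
            "no triple-junction equilibrium"
        )
    ratio = max(ratio, -1.0)
    return math.degrees(2.0 * math.acos(ratio))


def adhesion_from_angle(Gamma_cm: float, Gamma_cc: float, theta: float) -> float:
    """Adhesion energy J from cortical tensions and the contact angle (mN/m).

    Combines gamma_cc = 2*Gamma_cc - J with the Young balance
    gamma_cc = 2*Gamma_cm*cos(theta/2):

        J = 2*Gamma_cc - 2*Gamma_cm*cos(theta/2)

    For a wild-type angle of 180 degrees the cosine vanishes and
    J = 2*Gamma_cc.
    """
    return 2.0 * Gamma_cc - 2.0 * Gamma_cm * math.cos(math.radians(theta) / 2.0)


def solve_tensions(
    sigma_wt: float, sigma_uniform: float, theta_wt: float
) -> TensionSet:
    """Extract (Gamma_cm, Gamma_cc, J) from two TSTs and one contact angle.

    Parameters
    ----------
    sigma_wt : float
        TST of the condition whose cortical tensions are sought (mN/m).
    sigma_uniform : float
        TST of a uniform-cortex condition (Gamma_cm == Gamma_cc, e.g. a
        contractility-abolished mutant or myosin-inhibited tissue), which
        pins the adhesion energy through sigma = J/2 (mN/m).
    theta_wt : float
        Contact angle of the first condition (degrees), 0 < theta <= 180.

    Returns
    -------
    TensionSet
        J = 2*sigma_uniform, Gamma_cm = sigma_wt / (1 - cos(theta/2)),
        Gamma_cc = Gamma_cm*cos(theta/2) + sigma_uniform.  Round-trips
        exactly through the forward maps.
    """
    if sigma_wt <= 0 or sigma_uniform <= 0:
        raise ValueError("surface tensions must be positive")
    if not 0.0 < theta_wt <= 180.0:
        raise ValueError("theta_wt must lie in (0, 180] degrees")
    c = math.cos(math.radians(theta_wt) / 2.0)
    if math.isclose(c, 1.0):
        raise ValueError("theta_wt = 0 makes Gamma_cm diverge")
    J = 2.0 * sigma_uniform
    Gamma_cm = sigma_wt / (1.0 - c)
    Gamma_cc = Gamma_cm * c + sigma_uniform
    return TensionSet(Gamma_cm=Gamma_cm, Gamma_cc=Gamma_cc, J=J)


def decompose_tst(t: TensionSet) -> tuple[float, float]:
    """Split sigma into contractility and adhesion fractions.

    Returns ``((Gamma_cm - Gamma_cc)/sigma, (J/2)/sigma)``; the two always
    sum to 1.  Raises ``ValueError`` when sigma == 0.
    """
    sigma = tst_from_tensions(t)
    if sigma == 0:
        raise ValueError("sigma is zero: decomposition undefined")
    return (t.Gamma_cm - t.Gamma_cc) / sigma, (0.5 * t.J) / sigma
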