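"""The twelve mechanical states of intestinal circular muscle.

At one place and time the muscle's mechanical behaviour is classified by the
joint direction of change of gut diameter and intraluminal pressure, together
with whether the diameter is occluded (near its recorded minimum) or distended.
Each state is a triple of *state components*: one for the diameter value ``d``
(``any``/``dis``/``occ``) and one each for the diameter and pressure rates of
change ``d_dot`` and ``p_dot`` (``quiet``/``pos``/``neg``).

The canonical ordering of :class:`MechanicalState` (its integer ``value``) is
used everywhere for integer-coded state maps and for deterministic
tie-breaking in decoding.
"""

from __future__ import annotations

from enum import Enum

import numpy as np

__all__ = [
    "DiameterComponent",
    "VelocityComponent",
    "MechanicalState",
    "STATES",
    "N_STATES",
    "state_components",
]


class DiameterComponent(Enum):
    """Classification of the diameter value: irrelevant, distended or occluded."""

    ANY = "any"
    DIS = "dis"
    OCC = "occ"


class VelocityComponent(Enum):
    """Classification of a rate of change: near zero, positive or negative."""

    QUIET = "quiet"
    POS = "pos"
    NEG = "neg"


_D = DiameterComponent
_V = VelocityComponent

# name -> (c_d, c_d_dot, c_p_dot); the bijection defining the state space.
_COMPONENTS = {
    "OIMC": (_D.OCC, _V.QUIET, _V.POS),
    "OIMR": (_D.OCC, _V.QUIET, _V.NEG),
    "DIPI": (_D.DIS, _V.QUIET, _V.POS),
    "DIPD": (_D.DIS, _V.QUIET, _V.NEG),
    "ITC": (_D.ANY, _V.NEG, _V.QUIET),
    "ITR": (_D.ANY, _V.POS, _V.QUIET),
    "ATC": (_D.ANY, _V.NEG, _V.POS),
    "ATR": (_D.ANY, _V.POS, _V.NEG),
    "PS": (_D.ANY, _V.NEG, _V.NEG),
    "PD": (_D.ANY, _V.POS, _V.POS),
    "OQ": (_D.OCC, _V.QUIET, _V.QUIET),
    "DQ": (_D.DIS, _V.QUIET, _V.QUIET),
}

_LONG_NAMES = {
    "OIMC": "occluded isometric contraction",
    "OIMR": "occluded isometric relaxation",
    "DIPI": "distended isometric pressure increase",
    "DIPD": "distended isometric pressure decrease",
    "ITC": "isotonic contraction",
    "ITR": "isotonic relaxation",
    "ATC": "auxotonic contraction",
    "ATR": "auxotonic relaxation",
    "PS": "passive shortening",
    "PD": "passive dilation",
    "OQ": "occluded quiescence",
    "DQ": "distended quiescence",
}

# States whose behaviour requires muscle activation (contraction or active
# relaxation); the remaining seven are passive.
_ACTIVE = {"OIMC", "ITC", "ITR", "ATC", "ATR"}


class MechanicalState(Enum):
    """One of the twelve mechanical muscle states, in canonical order."""

    OIMC = 0
    OIMR = 1
    DIPI = 2
    DIPD = 3
    ITC = 4
    ITR = 5
    ATC = 6
    ATR = 7
    PS = 8
    PD = 9
    OQ = 10
    DQ = 11

    @property
    def components(self) -> tuple[DiameterComponent, VelocityComponent, VelocityComponent]:
        """The (c_d, c_d_dot, c_p_dot) component triple of this state."""
        return _COMPONENTS[self.name]

    @property
    def diameter_component(self) -> DiameterComponent:
        return _COMPONENTS[self.name][0]

    @property
    def d_velocity_component(self) -> VelocityComponent:
        return _COMPONENTS[self.name][1]

    @property
    def p_velocity_component(self) -> VelocityComponent:
        return _COMPONENTS[self.name][2]

    @property
    def long_name(self) -> str:
        return _LONG_NAMES[self.name]

    @property
    def is_active(self) -> bool:
        """Whether the state requires muscle activation."""
        return self.name in _ACTIVE

    @property
    def label(self) -> str:
        """Lower-case short label as used in the literature (e.g. ``'oimc'``)."""
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "MechanicalState":
        return cls[label.strip().upper()]


STATES: tuple[MechanicalState, ...] = tuple(MechanicalState)
N_STATES: int = len(STATES)


def state_components(state: MechanicalState):
    """Return the (c_d, c_d_dot, c_p_dot) triple of *state*."""
    return state.components


# Integer component-index tables used to assemble emission matrices.
# Diameter components are indexed in the order (any, dis, occ) and velocity
# components in the order (quiet, pos, neg).
_D_ORDER = (_D.ANY, _D.DIS, _D.OCC)
_V_ORDER = (_V.QUIET, _V.POS, _V.NEG)

DIAMETER_COMPONENT_INDEX = np.array(
    [_D_ORDER.index(s.diameter_component) for s in STATES], dtype=np.intp
)
DVEL_COMPONENT_INDEX = np.array(
    [_V_ORDER.index(s.d_velocity_component) for s in STATES], dtype=np.intp
)
PVEL_COMPONENT_INDEX = np.array(
    [_V_ORDER.index(s.p_velocity_component) for s in STATES], dtype=np.intp
)
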