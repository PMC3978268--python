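"""Plastochron loop: from kinetic rules to a whole-plant ontogeny.

Drives all active meristems tick by tick, builds the meristem tree and
records an ordered event log from which the zigzag vegetativeness
trajectories can be re-plotted.

Tick semantics (fixed, documented conventions):

* Ticks are 0-based; the primary shoot apical meristem (SAM, the root of
  the tree) is born at tick 0 with level ``v0``.
* Per tick, every active meristem — visited in birth order — first steps
  its level (with ``dv_pre`` while it has never left the vegetative band,
  ``dv_post`` afterwards), is then reclassified, and then either commits
  (identity floral: it becomes a flower and produces nothing) or produces
  exactly one phytomer.
* The phytomer produced on the tick a meristem first crosses the
  floral-transition threshold is its *last leaf*: its primordium was laid
  down while the meristem was still vegetative, and its axillary meristem
  is the sympodial meristem (SYM) that will continue the shoot.  The
  first inflorescence phytomer follows one plastochron later.
* An inflorescence phytomer carries a lateral meristem initiated at the
  parent's post-step level plus ``delta_v``.  A lateral born at or above
  the transition threshold is a vegetative axis: it is counted, logged as
  a reversion, and never simulated further.  Other laterals begin
  stepping on the following tick.
* Axillary meristems of leaf phytomers (including the SYM) are implied by
  the leaf events in the log but are not instantiated: only the primary
  inflorescence is simulated.
* The simulation ends when no meristem is active or ``horizon``
  plastochrons after the root's floral transition, whichever comes first;
  survivors are censored.

The loop contains no randomness: identical parameters yield identical
event logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional

import pandas as pd

from .exceptions import MeristemCapError
from .kinetics import (
    Identity,
    ModelParams,
    lateral_initial_level,
    meristem_identity,
    step_vegetativeness,
)

__all__ = [
    "Fate",
    "EventKind",
    "Event",
    "Meristem",
    "Ontogeny",
    "simulate_plant",
    "vegetativeness_trajectories",
]

ROOT_ID = 0


class Fate(str, Enum):
    """Terminal (or pending) fate of a meristem."""

    ACTIVE = "active"
    FLOWER = "flower"
    VEGETATIVE_AXIS = "vegetative-axis"
    CENSORED = "censored"


class EventKind(str, Enum):
    BIRTH = "birth"
    LEAF_PHYTOMER = "leaf-phytomer"
    INFLORESCENCE_PHYTOMER = "inflorescence-phytomer"
    FLORAL_TRANSITION = "floral-transition"
    COMMITMENT = "commitment"
    REVERSION = "reversion"
    CENSORED = "censored"


@dataclass(frozen=True)
class Event:
    tick: int
    meristem_id: int
    kind: EventKind


@dataclass
class Meristem:
    """One meristem: identity, fate and full vegetativeness trajectory."""

    id: int
    parent_id: Optional[int]
    birth_tick: int
    birth_level: float
    identity_at_birth: Identity
    generation: int
    level: float = field(init=False)
    fate: Fate = Fate.ACTIVE
    trajectory: list[tuple[int, float]] = field(default_factory=list)
    children: list[int] = field(default_factory=list)
    # True once the meristem has left the vegetative band (laterals are
    # born outside it and start True); selects dv_pre vs dv_post.
    post_transition: bool = field(init=False)

    def __post_init__(self) -> None:
        self.level = self.birth_level
        self.trajectory.append((self.birth_tick, self.birth_level))
        self.post_transition = self.identity_at_birth is not Identity.VEGETATIVE


@dataclass
class Ontogeny:
    """A fully simulated plant: parameter echo, meristem registry, event log."""

    params: ModelParams
    meristems: dict[int, Meristem]
    events: list[Event]
    transition_tick: Optional[int]
    final_tick: int

    @property
    def root(self) -> Meristem:
        return self.meristems[ROOT_ID]

    def by_fate(self, fate: Fate) -> list[Meristem]:
        return [m for m in self.meristems.values() if m.fate is fate]

    def __iter__(self) -> Iterator[Meristem]:
        return iter(self.meristems.values())


def simulate_plant(params: ModelParams) -> Ontogeny:
    """Deterministically simulate one plant under the given parameters.

    Returns the complete :class:`Ontogeny`.  Every meristem reaches
    exactly one terminal fate (flower, vegetative axis, or censored), so
    the fates always partition the registry.

    Raises
    ------
    MeristemCapError
        If the meristem registry exceeds ``params.max_meristems``.
    """
    root = Meristem(
        id=ROOT_ID,
        parent_id=None,
        birth_tick=0,
        birth_level=params.v0,
        identity_at_birth=meristem_identity(params.v0, params),
        generation=0,
    )
    meristems: dict[int, Meristem] = {ROOT_ID: root}
    events: list[Event] = [Event(0, ROOT_ID, EventKind.BIRTH)]
    active: list[Meristem] = [root]
    transition_tick: Optional[int] = None
    tick = 0

    while active:
        if transition_tick is not None and tick >= transition_tick + params.horizon:
            break
        tick += 1
        newborn: list[Meristem] = []
        for m in active:
            was_vegetative = not m.post_transition
            dv = params.dv_pre if was_vegetative else params.dv_post
            m.level = step_vegetativeness(m.level, dv)
            m.trajectory.append((tick, m.level))
            identity = meristem_identity(m.level, params)

            if was_vegetative and identity is not Identity.VEGETATIVE:
                m.post_transition = True
                events.append(Event(tick, m.id, EventKind.FLORAL_TRANSITION))
                if m.id == ROOT_ID:
                    transition_tick = tick

            if identity is Identity.FLORAL:
                m.fate = Fate.FLOWER
                events.append(Event(tick, m.id, EventKind.COMMITMENT))
            elif identity is Identity.VEGETATIVE or was_vegetative:
                # still vegetative, or the transition-tick last leaf
                events.append(Event(tick, m.id, EventKind.LEAF_PHYTOMER))
            else:
                child_level = lateral_initial_level(m.level, params.delta_v)
                child = Meristem(
                    id=len(meristems),
                    parent_id=m.id,
                    birth_tick=tick,
                    birth_level=child_level,
                    identity_at_birth=meristem_identity(child_level, params),
                    generation=m.generation + 1,
                )
                meristems[child.id] = child
                m.children.append(child.id)
                events.append(Event(tick, m.id, EventKind.INFLORESCENCE_PHYTOMER))
                events.append(Event(tick, child.id, EventKind.BIRTH))
                if child.identity_at_birth is Identity.VEGETATIVE:
                    child.fate = Fate.VEGETATIVE_AXIS
                    events.append(Event(tick, child.id, EventKind.REVERSION))
                else:
                    newborn.append(child)
                if len(meristems) > params.max_meristems:
                    raise MeristemCapError(
                        f"meristem cap {params.max_meristems} exceeded at tick "
                        f"{tick} (dv_post={params.dv_post}, "
                        f"delta_v={params.delta_v})"
                    )
        active = [m for m in active if m.fate is Fate.ACTIVE] + newborn

    for m in active:
        m.fate = Fate.CENSORED
        events.append(Event(tick, m.id, EventKind.CENSORED))

    return Ontogeny(
        params=params,
        meristems=meristems,
        events=events,
        transition_tick=transition_tick,
        final_tick=tick,
    )


def vegetativeness_trajectories(ontogeny: Ontogeny) -> pd.DataFrame:
    """Tidy table of the zigzag trajectories of every simulated meristem.

    One row per recorded (tick, level) point, including the birth point,
    with the identity band re-derived from the level.  Suitable for
    plotting vegetativeness decline of successive meristems against
    plastochron time.
    """
    rows = []
    for m in ontogeny.meristems.values():
        for tick, level in m.trajectory:
            rows.append(
                {
                    "meristem_id": m.id,
                    "tick": tick,
                    "level": level,
                    "identity": meristem_identity(level, ontogeny.params).value,
                }
            )
    return pd.DataFrame(rows, columns=["meristem_id", "tick", "level", "identity"])
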