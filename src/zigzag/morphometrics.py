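"""Topology metrics of a simulated inflorescence and morphotype assignment.

Three metrics summarise a primary inflorescence:

* number of flowers before the first vegetative reversion (all flowers if
  the inflorescence never reverts),
* branching level: the number of phytomers the transitional meristem (the
  root after floral transition) initiated before committing to a flower,
* number of vegetative axes.

Counting "before the first reversion" is done in birth order: a flower
counts if its meristem was initiated before the first vegetative lateral
was initiated, even when its commitment event is logged later.  This
reproduces the one-to-few-flower phenotypes where the primary flower
precedes the reversion in the zigzag although it commits afterwards.

Each metric is discretised into printed classes (flowers 0 / 1 / >=2;
branching 0 / 1 / 2-5 / >=6; vegetative axes 0 / >=1) and the class
triple is looked up in the eight-row morphotype table.  The sixteen
remaining triples are deliberately reported as unclassified rather than
coerced to the nearest morphotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .simulator import EventKind, Fate, Ontogeny, ROOT_ID

__all__ = [
    "InflorescenceMetrics",
    "MorphotypeClass",
    "MORPHOTYPE_TABLE",
    "UNCLASSIFIED",
    "compute_metrics",
    "discretize",
    "morphotype_of",
]

UNCLASSIFIED = "unclassified"

#: Class-triple -> morphotype id.  (flower_class, branching_class, veg_class)
MORPHOTYPE_TABLE: dict[tuple[str, str, str], int] = {
    (">=2", "2-5", "0"): 1,
    ("0", ">=6", "0"): 2,
    ("0", ">=6", ">=1"): 3,
    (">=2", "2-5", ">=1"): 4,
    ("1", "1", ">=1"): 5,
    (">=2", "1", ">=1"): 6,
    ("1", "0", "0"): 7,
    (">=2", "1", "0"): 8,
}


@dataclass(frozen=True)
class InflorescenceMetrics:
    """Raw topology counts of one simulated primary inflorescence."""

    flowers_before_reversion: int
    branching_level: int
    vegetative_axes: int
    leaves_before_transition: int
    total_flowers: int
    censored: int
    no_transition: bool = False

    def __post_init__(self) -> None:
        counts = (
            self.flowers_before_reversion,
            self.branching_level,
            self.vegetative_axes,
            self.leaves_before_transition,
            self.total_flowers,
            self.censored,
        )
        if any(c < 0 for c in counts):
            raise ValueError(f"metrics must be non-negative, got {self}")
        if self.flowers_before_reversion > self.total_flowers:
            raise ValueError(
                "flowers_before_reversion cannot exceed total_flowers"
            )


@dataclass(frozen=True)
class MorphotypeClass:
    """Discretised metric classes plus the resulting morphotype id.

    ``morphotype`` is an integer 1-8 when the class triple matches a row
    of :data:`MORPHOTYPE_TABLE` and ``None`` (unclassified) otherwise.
    """

    flower_class: str
    branching_class: str
    veg_class: str
    morphotype: Optional[int]

    @property
    def label(self) -> str:
        return UNCLASSIFIED if self.morphotype is None else str(self.morphotype)


def compute_metrics(ontogeny: Ontogeny) -> InflorescenceMetrics:
    """Measure the three topology metrics (plus bookkeeping counts).

    If the root never underwent floral transition the inflorescence does
    not exist: flowers and branching are zero and the result is flagged
    ``no_transition``.
    """
    root = ontogeny.root
    leaves = sum(
        1
        for ev in ontogeny.events
        if ev.kind is EventKind.LEAF_PHYTOMER and ev.meristem_id == ROOT_ID
    )
    flowers = ontogeny.by_fate(Fate.FLOWER)
    veg_axes = ontogeny.by_fate(Fate.VEGETATIVE_AXIS)
    censored = len(ontogeny.by_fate(Fate.CENSORED))

    if veg_axes:
        first_reversion_birth = min(m.birth_tick for m in veg_axes)
        flowers_before = sum(
            1 for m in flowers if m.birth_tick < first_reversion_birth
        )
    else:
        flowers_before = len(flowers)

    return InflorescenceMetrics(
        flowers_before_reversion=flowers_before,
        branching_level=len(root.children),
        vegetative_axes=len(veg_axes),
        leaves_before_transition=leaves,
        total_flowers=len(flowers),
        censored=censored,
        no_transition=ontogeny.transition_tick is None,
    )


def _flower_class(n: int) -> str:
    if n == 0:
        return "0"
    if n == 1:
        return "1"
    return ">=2"


def _branching_class(n: int) -> str:
    if n == 0:
        return "0"
    if n == 1:
        return "1"
    if n <= 5:
        return "2-5"
    return ">=6"


def _veg_class(n: int) -> str:
    return "0" if n == 0 else ">=1"


def discretize(metrics: InflorescenceMetrics) -> MorphotypeClass:
    """Map raw counts onto the printed classes and assign the morphotype."""
    triple = (
        _flower_class(metrics.flowers_before_reversion),
        _branching_class(metrics.branching_level),
        _veg_class(metrics.vegetative_axes),
    )
    return MorphotypeClass(*triple, morphotype=MORPHOTYPE_TABLE.get(triple))


def morphotype_of(cls: MorphotypeClass) -> Optional[int]:
    """Morphotype id of a class triple; ``None`` when no row matches."""
    return MORPHOTYPE_TABLE.get(
        (cls.flower_class, cls.branching_class, cls.veg_class)
    )
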