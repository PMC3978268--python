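"""Maturation kinetics of a single meristem.

The model tracks each meristem by a single abstract state variable, its
*vegetativeness* ``V``: high values correspond to shoot (leaf-producing)
identity, low values to flower identity.  Time is discrete and measured in
plastochrons, the interval between the initiation of two successive
phytomers.  Three rules govern the kinetics:

1. Vegetativeness decays once per plastochron following the nonlinear
   recurrence ``V_i = V_{i-1} - dV / V_{i-1}``, where ``dV`` is the
   maturation rate.  The per-tick decrement ``dV / V`` grows as ``V``
   falls, so maturation accelerates toward commitment; this acceleration
   is what terminates flower production in a wild-type truss.
2. Two fixed thresholds partition the vegetativeness axis into identity
   bands: *vegetative* (leaf production) at or above the floral-transition
   threshold, *inflorescence* between the two thresholds, and *floral*
   (irreversibly committed to making a flower) strictly below the
   floral-commitment threshold.
3. A lateral meristem starts life one vegetativeness gain ``delta_v``
   above the current level of the meristem that initiated it,
   ``V'_0 = V_p + delta_v``.  This upward jump followed by renewed decay
   is what gives simulated trajectories their zigzag shape.

The maturation rate may differ before and after the floral transition of
the primary shoot apical meristem (``dv_pre`` vs. ``dv_post``): the
pre-transition rate sets flowering time (leaf number), the post-transition
rate shapes inflorescence architecture.

Everything in this module is a pure function of its arguments; the
plastochron loop that wires the rules into a whole plant lives in
:mod:`zigzag.simulator`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from enum import Enum

from .exceptions import InvalidStateError, NeverCrossesError

__all__ = [
    "ModelParams",
    "Identity",
    "step_vegetativeness",
    "lateral_initial_level",
    "meristem_identity",
    "ticks_to_cross",
    "continuous_crossing_time",
]


@dataclass(frozen=True)
class ModelParams:
    """Kinetic constants and thresholds of the zigzag model.

    The default values are the package's wild-type calibration.  They are
    chosen so that the simulated wild type initiates 6-12 leaves before
    floral transition and then makes a finite, unbranched, multi-flower
    truss without vegetative reversion; see ``docs/methods.md`` for the
    calibration rationale.  All vegetativeness quantities are
    dimensionless; rates are per plastochron.

    Parameters
    ----------
    v0 : float
        Vegetativeness of the shoot apical meristem at germination.
    dv_pre : float
        Maturation rate before the floral transition of the primary SAM.
        Must be strictly positive (the plant must eventually flower).
    dv_post : float
        Maturation rate after the floral transition.  May be zero, in
        which case inflorescence meristems never commit and the run is
        censored at the horizon.
    delta_v : float
        Vegetativeness gain of a newly initiated lateral meristem over
        the current level of its parent.
    t_transition : float
        Floral-transition threshold.  Leaf production is repressed below
        it; a lateral initiated at or above it reverts to a vegetative
        axis.
    t_commitment : float
        Floral-commitment threshold.  A meristem whose level falls
        strictly below it becomes a flower and initiates nothing more.
    horizon : int
        Number of plastochrons simulated after the floral transition of
        the primary SAM (the inflorescence-development window).  Meristems
        still active at the horizon are censored.
    max_meristems : int
        Safety cap on the total number of meristems in one simulation.
    """

    v0: float = 5.0
    dv_pre: float = 0.55
    dv_post: float = 4.5
    delta_v: float = 0.05
    t_transition: float = 4.0
    t_commitment: float = 1.5
    horizon: int = 12
    max_meristems: int = 100_000

    def __post_init__(self) -> None:
        if not (0.0 < self.t_commitment < self.t_transition < self.v0):
            raise ValueError(
                "thresholds must satisfy 0 < t_commitment < t_transition < v0, "
                f"got t_commitment={self.t_commitment}, "
                f"t_transition={self.t_transition}, v0={self.v0}"
            )
        if self.dv_pre <= 0.0:
            raise ValueError(f"dv_pre must be > 0, got {self.dv_pre}")
        if self.dv_post < 0.0:
            raise ValueError(f"dv_post must be >= 0, got {self.dv_post}")
        if self.delta_v < 0.0:
            raise ValueError(f"delta_v must be >= 0, got {self.delta_v}")
        if int(self.horizon) != self.horizon or self.horizon < 1:
            raise ValueError(f"horizon must be an integer >= 1, got {self.horizon}")
        if int(self.max_meristems) != self.max_meristems or self.max_meristems < 1:
            raise ValueError(
                f"max_meristems must be an integer >= 1, got {self.max_meristems}"
            )

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class Identity(str, Enum):
    """Identity band of a meristem, read off its vegetativeness level.

    The ordering vegetative > inflorescence > floral mirrors descending
    vegetativeness.  Boundary convention: a level exactly at the
    floral-transition threshold is *vegetative* (>= at the upper
    threshold); a level exactly at the floral-commitment threshold is
    *inflorescence* (strict < at the lower threshold).  Fixing ">=" at
    the top makes ``delta_v = 0`` provably reversion-free: a lateral then
    starts exactly at its parent's sub-threshold level.
    """

    VEGETATIVE = "vegetative"
    INFLORESCENCE = "inflorescence"
    FLORAL = "floral"


def step_vegetativeness(v: float, dv: float) -> float:
    """Advance a vegetativeness level by one plastochron.

    Returns ``v - dv / v``.  The result may be arbitrarily low (including
    negative); the caller must treat any value below the commitment
    threshold as committed and never step that meristem again.

    Raises
    ------
    InvalidStateError
        If ``v <= 0``: such a meristem is terminal and stepping it would
        hit the singularity of ``dv / v``.
    ValueError
        If ``dv < 0``.
    """
    if v <= 0.0:
        raise InvalidStateError(
            f"cannot step a committed/terminal meristem (v={v} <= 0)"
        )
    if dv < 0.0:
        raise ValueError(f"maturation rate must be >= 0, got {dv}")
    return v - dv / v


def lateral_initial_level(v_parent: float, delta_v: float) -> float:
    """Vegetativeness at which a new lateral meristem is initiated.

    The lateral starts ``delta_v`` above the current level of the meristem
    that produced the phytomer: ``V'_0 = V_p + delta_v``.

    Raises
    ------
    InvalidStateError
        If ``v_parent <= 0`` (a committed meristem cannot initiate).
    ValueError
        If ``delta_v < 0``.
    """
    if v_parent <= 0.0:
        raise InvalidStateError(
            f"a committed meristem cannot initiate a lateral (v_parent={v_parent})"
        )
    if delta_v < 0.0:
        raise ValueError(f"delta_v must be >= 0, got {delta_v}")
    return v_parent + delta_v


def meristem_identity(v: float, params: ModelParams) -> Identity:
    """Classify a vegetativeness level into its identity band.

    Total and piecewise-constant with exactly two breakpoints:
    vegetative iff ``v >= t_transition``; floral iff ``v < t_commitment``;
    inflorescence in between (including ``v == t_commitment``).
    """
    if v >= params.t_transition:
        return Identity.VEGETATIVE
    if v >= params.t_commitment:
        return Identity.INFLORESCENCE
    return Identity.FLORAL


def continuous_crossing_time(v0: float, dv: float, threshold: float) -> float:
    """Continuous-limit estimate of the threshold-crossing time.

    Treating the recurrence as the ODE ``dV/dt = -dv / V`` gives
    ``V(t)^2 = v0^2 - 2 dv t``, hence the level reaches ``threshold`` at
    ``t* = (v0^2 - threshold^2) / (2 dv)``.  The discrete recurrence
    always crosses at or after ``t*`` (each discrete step is taken at the
    tick's starting level, which overestimates ``V`` along the step), so
    ``ceil(t*)`` is a lower bound on :func:`ticks_to_cross`.
    """
    if dv <= 0.0:
        raise NeverCrossesError("continuous crossing time undefined for dv <= 0")
    return (v0 * v0 - threshold * threshold) / (2.0 * dv)


def ticks_to_cross(v0: float, dv: float, threshold: float) -> int:
    """Exact number of plastochrons until the level first falls below a threshold.

    Iterates :func:`step_vegetativeness` from ``v0`` and returns the
    smallest ``n`` such that the level after ``n`` steps is strictly below
    ``threshold``.  Returns 0 if ``v0`` already lies below the threshold.
    Used as an independent oracle for the simulator (e.g. the flowerless
    region of the morphospace is exactly where the commitment-crossing
    time from the transition threshold exceeds the horizon).

    Raises
    ------
    NeverCrossesError
        If ``dv == 0`` while ``threshold <= v0`` (constant level).
    ValueError
        If ``threshold <= 0`` (the recurrence is singular at zero, so a
        non-positive threshold has no well-defined crossing count).
    """
    if threshold > v0:
        return 0
    if threshold <= 0.0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    if dv == 0.0:
        raise NeverCrossesError(
            f"level {v0} never crosses {threshold} at zero maturation rate"
        )
    v = v0
    n = 0
    # dv > 0 implies each step shrinks v by at least dv / v0, so the loop
    # terminates within ceil(v0^2 / dv) iterations.
    while v >= threshold:
        v = step_vegetativeness(v, dv)
        n += 1
    return n


def _continuous_tick_estimate(v0: float, dv: float, threshold: float) -> int:
    """Closed-form crossing estimate rounded up to a whole tick count."""
    return math.ceil(continuous_crossing_time(v0, dv, threshold))
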