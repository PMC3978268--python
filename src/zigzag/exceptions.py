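"""Exception hierarchy for the zigzag package."""


class ZigzagError(Exception):
    """Base class for all package-specific errors."""


class InvalidStateError(ZigzagError):
    """A kinetic operation was applied to a meristem in a terminal state.

    Raised when the maturation step is requested for a vegetativeness level
    at or below zero: a meristem that low has long passed floral commitment
    and must be frozen, otherwise the ``dv / v`` term becomes singular.
    """


class NeverCrossesError(ZigzagError):
    """A threshold-crossing time was requested for a non-maturing meristem.

    With a zero maturation rate the vegetativeness level is constant, so a
    threshold strictly below the starting level is never reached.
    """


class MeristemCapError(ZigzagError):
    """The simulation exceeded the configured meristem safety cap.

    Expected only for near-zero post-transition maturation rates combined
    with a long horizon, where every meristem keeps branching every
    plastochron and the ontogeny grows geometrically.
    """


class UnknownGeneError(ZigzagError):
    """A genotype referenced a gene with no registered preset."""


class DuplicateGeneError(ZigzagError):
    """A genotype listed two conflicting alleles of the same gene."""


class ConfigError(ZigzagError):
    """A run configuration contained unknown or invalid keys."""
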