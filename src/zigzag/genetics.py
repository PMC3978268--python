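"""Genotype-to-parameter mapping: mutant presets and their combination.

Each flowering-time/inflorescence gene of tomato is summarised by the
direction in which its loss (or overexpression) shifts the two model
variables: the post-transition maturation rate ``dv_post`` and the
lateral vegetativeness gain ``delta_v``.  A genotype is resolved into a
parameter vector by adding the single-mutant contributions to the
wild-type vector, with one exception: mutations whose maturation rate sits
at an extreme of the morphospace are not averaged with intermediate rates
but *clamp* the resolved rate to that extreme.  Loss of the flower-meristem
identity genes *AN* or *FA* pins the rate to a near-zero floor (their
meristems never acquire flower identity), while loss of *TMF* pins the
rate of the primary transitional meristem to a high ceiling (precocious
commitment).  The floor wins over the ceiling, encoding the observed
epistasis of *fa* over *tmf*.  Vegetativeness-gain contributions stay
additive even under clamping.

Preset magnitudes are calibration constants of this package: the
underlying genetic analyses constrain only the signs and the qualitative
placement of each mutant in the morphospace.  The shipped table satisfies
the single- and double-mutant placements and is pinned by the test suite;
see ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

from .exceptions import DuplicateGeneError, UnknownGeneError
from .kinetics import ModelParams
from .morphometrics import InflorescenceMetrics, compute_metrics, discretize
from .simulator import simulate_plant

__all__ = [
    "DvMode",
    "Allele",
    "Scope",
    "GenePreset",
    "Genotype",
    "PRESETS",
    "DV_MIN_FRACTION",
    "DV_MAX",
    "parse_genotype",
    "resolve_genotype",
    "predict_phenotype",
]


class DvMode(str, Enum):
    ADDITIVE = "additive"
    CLAMP_MIN = "clamp-min"
    CLAMP_MAX = "clamp-max"


class Allele(str, Enum):
    LOSS_OF_FUNCTION = "loss-of-function"
    OVEREXPRESSION = "overexpression"


class Scope(str, Enum):
    """Phase of the plant the preset acts on.

    ``PLANT`` affects the whole simulated run; ``PRIMARY`` marks presets
    whose description is valid for the SAM of the initial segment only
    (loss of *TMF*, constitutive overexpression).  Because this package
    simulates only the primary inflorescence, the distinction is
    bookkeeping here, but it matters for any extension to later sympodial
    segments.
    """

    PLANT = "whole-plant"
    PRIMARY = "primary-SAM-only"


@dataclass(frozen=True)
class GenePreset:
    """Contribution of one allele to the model's parameter vector.

    ``dv_effect`` applies to ``dv_post`` (ignored under a clamp mode,
    where the resolved rate is pinned to the floor/ceiling instead);
    ``delta_effect`` adds to ``delta_v``; ``dv_pre_effect`` adds to the
    pre-transition rate and encodes early-flowering alleles.
    """

    gene: str
    allele: Allele = Allele.LOSS_OF_FUNCTION
    dv_mode: DvMode = DvMode.ADDITIVE
    dv_effect: float = 0.0
    delta_effect: float = 0.0
    dv_pre_effect: float = 0.0
    scope: Scope = Scope.PLANT


# Calibrated preset table.  Signs follow the inferred gene contributions
# (a gene that promotes maturation loses rate when mutated; a gene that
# represses the lateral gain raises it when mutated):
#   AN  : dv +          -> lof clamps dv_post to the near-zero floor
#   FA  : dv +, delta - -> lof clamps dv_post to the floor and raises delta_v
#   S   : dv +          -> lof lowers dv_post (additive)
#   SFT : delta -       -> lof raises delta_v
#   J   : dv -, delta - -> lof raises both (additive)
#   TMF : dv -, delta + -> lof clamps dv_post to the high ceiling, slightly
#         lowers delta_v, and accelerates the pre-transition phase
#         (early flowering); primary-segment scope.
PRESETS: dict[str, GenePreset] = {
    "an": GenePreset("AN", dv_mode=DvMode.CLAMP_MIN),
    "fa": GenePreset("FA", dv_mode=DvMode.CLAMP_MIN, delta_effect=+0.60),
    "s": GenePreset("S", dv_effect=-2.3),
    "sft": GenePreset("SFT", delta_effect=+1.45),
    "j": GenePreset("J", dv_effect=+2.0, delta_effect=+1.90),
    "tmf": GenePreset(
        "TMF",
        dv_mode=DvMode.CLAMP_MAX,
        delta_effect=-0.03,
        dv_pre_effect=+0.65,
        scope=Scope.PRIMARY,
    ),
    "35S:FA": GenePreset(
        "FA",
        allele=Allele.OVEREXPRESSION,
        dv_pre_effect=+0.65,
        scope=Scope.PRIMARY,
    ),
    "35S:SFT": GenePreset(
        "SFT",
        allele=Allele.OVEREXPRESSION,
        dv_pre_effect=+0.65,
        scope=Scope.PRIMARY,
    ),
}

#: Clamp floor for near-null maturation, as a fraction of the wild-type rate.
#: Strictly positive: "close to zero", with branching kept finite only by
#: the horizon.
DV_MIN_FRACTION = 0.05
#: Clamp ceiling for precocious commitment of the transitional meristem.
DV_MAX = 12.0

_CANONICAL = {name.lower(): name for name in PRESETS}


@dataclass(frozen=True)
class Genotype:
    """An ordered set of allele presets; zygosity is fixed homozygous."""

    presets: tuple[GenePreset, ...]

    def __post_init__(self) -> None:
        genes = [p.gene for p in self.presets]
        dupes = {g for g in genes if genes.count(g) > 1}
        if dupes:
            raise DuplicateGeneError(
                f"conflicting alleles for gene(s): {', '.join(sorted(dupes))}"
            )

    @property
    def names(self) -> tuple[str, ...]:
        prefix = {Allele.OVEREXPRESSION: "35S:"}
        return tuple(
            prefix.get(p.allele, "") + p.gene.lower()
            if p.allele is Allele.LOSS_OF_FUNCTION
            else prefix[p.allele] + p.gene
            for p in self.presets
        )

    def __len__(self) -> int:
        return len(self.presets)


def parse_genotype(text: str | Iterable[str]) -> Genotype:
    """Build a genotype from a string like ``"sft j"`` or ``"35S:SFT"``.

    Tokens are separated by whitespace or commas and matched
    case-insensitively against the preset table.  The empty string is the
    wild type.
    """
    if isinstance(text, str):
        tokens = [t for t in text.replace(",", " ").split() if t]
    else:
        tokens = [t for t in text if t]
    presets = []
    for tok in tokens:
        key = _CANONICAL.get(tok.lower())
        if key is None:
            known = ", ".join(sorted(PRESETS))
            raise UnknownGeneError(f"unknown gene {tok!r}; known: {known}")
        presets.append(PRESETS[key])
    return Genotype(tuple(presets))


def resolve_genotype(
    genotype: Genotype,
    wt: ModelParams,
    dv_min: Optional[float] = None,
    dv_max: float = DV_MAX,
) -> ModelParams:
    """Resolve a genotype into a parameter vector by vector addition.

    ``delta_v`` = wild type plus the sum of the gain contributions,
    floored at 0.  ``dv_post`` = wild type plus the sum of the additive
    rate contributions, then pinned to ``dv_min`` if any floor-clamping
    allele is present, else to ``dv_max`` if any ceiling-clamping allele
    is present (the floor has priority).  ``dv_pre`` gains the
    early-flowering contributions.  The result is independent of gene
    order.
    """
    if dv_min is None:
        dv_min = DV_MIN_FRACTION * wt.dv_post
    delta_v = max(0.0, wt.delta_v + sum(p.delta_effect for p in genotype.presets))
    dv_pre = wt.dv_pre + sum(p.dv_pre_effect for p in genotype.presets)
    dv_post = wt.dv_post + sum(
        p.dv_effect for p in genotype.presets if p.dv_mode is DvMode.ADDITIVE
    )
    modes = {p.dv_mode for p in genotype.presets}
    if DvMode.CLAMP_MIN in modes:
        dv_post = dv_min
    elif DvMode.CLAMP_MAX in modes:
        dv_post = dv_max
    return wt.replace(dv_pre=dv_pre, dv_post=dv_post, delta_v=delta_v)


def predict_phenotype(
    genotype: Genotype, wt: ModelParams
) -> tuple[InflorescenceMetrics, Optional[int]]:
    """Resolve, simulate and classify: the predicted mutant phenotype.

    Returns the inflorescence metrics and the morphotype id (``None``
    when the class triple matches no morphotype row).  Deterministic.
    """
    params = resolve_genotype(genotype, wt)
    metrics = compute_metrics(simulate_plant(params))
    return metrics, discretize(metrics).morphotype
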