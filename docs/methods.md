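# Methods

## Model and assumptions

The simulator treats inflorescence development as a deterministic,
plastochron-discrete maturation process. Each meristem carries a single
scalar state, its vegetativeness `V`, standing in for the continuous
molecular maturation programme of real meristems. Assumptions worth
making explicit:

* Maturation is autonomous and identical in every meristem: the same
  rate `dV` applies to the transitional meristem and to every lateral
  inflorescence meristem (only the pre-/post-transition distinction is
  kept). No environmental input, no stochasticity, no dosage effects.
* The coupling between meristems is purely the initiation rule
  `V′₀ = V_p + ΔV`; there is no ongoing signalling between a parent and
  its laterals after birth.
* Identity is read instantaneously off `V` with two fixed thresholds.
  Boundary conventions are part of the model definition: *vegetative*
  iff `V ≥ t_transition` (so a lateral born exactly at the threshold
  reverts), *floral* iff `V < t_commitment` (so a meristem sitting
  exactly at commitment can still initiate one more phytomer). With
  these conventions `ΔV = 0` is provably reversion-free: every lateral
  is born at its parent's sub-threshold level.
* Committed meristems are frozen. The decrement `dV/V` is singular at
  `V = 0`; freezing at commitment keeps the recurrence well defined and
  encodes irreversibility.

### Tick schedule

Per plastochron, each active meristem (in birth order): steps its level,
is reclassified, then either commits (no phytomer) or produces exactly
one phytomer. Laterals initiated mid-tick begin stepping the following
tick, which prevents same-tick cascades. The parent level used at
initiation is the *post-step* level, matching zigzag trajectories in
which each lateral starts `ΔV` above its parent's current value.

The phytomer produced on the tick a meristem first crosses the
transition threshold is its last *leaf*: its primordium was laid down
while the meristem was still vegetative, and its axillary is the
sympodial meristem that continues the shoot. The first inflorescence
phytomer follows one plastochron later. This convention is load-bearing:
it is what allows a branching level of 0 (commitment on the first
post-transition step, the solitary-flower *tmf* pattern) and it makes
the default calibration produce an unbranched (branching 1) wild-type
truss. Treating the transition-tick phytomer as the first inflorescence
phytomer instead would force branching ≥ 1 for every genotype.

### Horizon and censoring

`horizon` counts plastochrons simulated *after* the root's floral
transition — it is the inflorescence-development window, not a total
clock. The vegetative phase runs as long as `dv_pre` dictates
(guaranteed finite for `dv_pre > 0`). The default horizon of 12 makes
the "≥6" branching class reachable and stands in for the unspecified
stopping rule of near-zero-rate genotypes, whose meristems never commit
and are censored. Meristem counts grow geometrically in that regime
(every active meristem branches every tick), which is why a
`max_meristems` cap (default 100 000, never reached on the default
grid; the worst default-grid cell holds 2¹² meristems) aborts a run
explicitly rather than letting it grow without bound.

## Calibration

Absolute scales are not identifiable from the qualitative constraints
the model must satisfy, so the wild-type constants are calibration
outputs of this package:

| parameter | default | role |
|---|---|---|
| `v0` | 5.0 | initial SAM vegetativeness (dimensionless) |
| `t_transition` | 4.0 | floral transition threshold |
| `t_commitment` | 1.5 | floral commitment threshold |
| `dv_pre` | 0.55 | pre-transition rate → 9 leaves before transition |
| `dv_post` | 4.5 | post-transition rate → unbranched 2-flower truss |
| `delta_v` | 0.05 | wild-type lateral gain → no reversion |
| `horizon` | 12 | post-transition window |

With these values the wild type initiates 9 leaves (target band 6–12),
transitions at `V ≈ 3.903`, initiates exactly one inflorescence phytomer
and terminates as a reversion-free two-flower truss (morphotype 8)
before the horizon. A noteworthy property of the recurrence: the
generation map for a single-file chain, `b ↦ b − dV/b + ΔV`, has an
*unstable* fixed point at `b* = dV/ΔV`, so long unbranched chains are
inherently transient — chains seeded below `b*` accelerate to
commitment, chains above it climb to reversion. Short wild-type trusses
are thus a structural feature, not a calibration accident.

### Mutant presets

The genetic analyses constrain only signs (which variable each gene
pushes, and in which direction) and qualitative morphospace placements.
Magnitudes below are calibration constants, pinned by the test suite:

| allele | dV mode | dV effect | ΔV effect | dv_pre effect |
|---|---|---|---|---|
| *an* | clamp-min | — | 0 | 0 |
| *fa* | clamp-min | — | +0.60 | 0 |
| *s* | additive | −2.3 | 0 | 0 |
| *sft* | additive | 0 | +1.45 | 0 |
| *j* | additive | +2.0 | +1.90 | 0 |
| *tmf* | clamp-max | — | −0.03 | +0.65 |
| 35S:*FA*, 35S:*SFT* | additive | 0 | 0 | +0.65 |

Clamp modes pin the resolved `dv_post` to an extreme instead of summing:
the floor `dv_min = 0.05 · dv_post(WT)` (strictly positive — "close to
zero" maturation, with branching kept finite only by the horizon) for
flower-identity nulls, the ceiling `dv_max = 12.0` for precocious
commitment. The floor wins over the ceiling, encoding the epistasis of
*fa* over *tmf*. ΔV contributions stay additive under clamping, and the
resolved ΔV is floored at 0. The *tmf* and overexpression presets also
raise `dv_pre` (early flowering, 4 leaves with the defaults); their
description is valid for the primary segment only, which is all this
package simulates.

### A structural limit of exact vector addition

One double mutant cannot land on its qualitative morphotype row under
*exact* parameter addition. For *s sft*, "many flowers plus vegetative
axes with intermediate branching" requires the transitional meristem's
first lateral to stay below the transition threshold; for *sft* alone,
"one flower then reversion" requires that same first lateral (at the
*higher* wild-type rate) to exceed it. Since lowering `dV` raises the
post-step level and hence the first lateral's birth level
(`V_T − dV/V_T + ΔV` is decreasing in `dV`), any ΔV that makes *sft*
revert at its first lateral makes *s sft* revert there too. The
simulated *s sft* nonetheless shows the described phenotype — 5 flowers
in total, branching 3, 7 vegetative axes — but its
flowers-*before-first-reversion* count is 1, so its class triple falls
outside the eight-row table. Mapping single mutants into their regions
involves exactly this kind of slack; the package keeps the single-mutant
placements exact and reports the double honestly.

## Numerical choices

* Pure float arithmetic, no tolerances anywhere in the model itself:
  classifications use the exact `≥`/`<` conventions above, and all
  calibrated margins were chosen away from boundaries (the closest is
  the *j s* commitment step, margin ≈ 0.011 vegetativeness units, exact
  and deterministic).
* `ticks_to_cross` iterates the recurrence exactly. The continuous limit
  `t* = (v0² − thr²)/(2 dV)` systematically *under*-estimates the
  discrete crossing (the discrete step uses the tick's starting level;
  the lag is ≈ ln(v0/thr)/2 ticks), so the exposed whole-tick estimate
  is `ceil(t*)`, which the exact count matches within one plastochron
  for every model-relevant crossing (thresholds well above the
  singularity, `dV ≤ 0.1 v0²`).
* The default morphospace grid is 40 × 30 (dV step 0.5 on (0, 20], ΔV
  evenly spaced on [0, 3]) for 1200 cells; `dV = 0` exactly is excluded
  from the grid (commitment impossible) but available directly through
  the simulator. Grid values are rounded to 6 decimals so CSV output is
  stable and keys compare exactly.
* Determinism end to end: no RNG, sorted JSON keys, LF endings — reruns
  are byte-identical and tested by hashing.

## What the simulations do and do not show

All inputs are parameters; there is no external data. Passing tests
show that the rule set with the calibrated constants reproduces the
qualitative genotype-to-architecture map: they do not validate the
constants against measured maturation kinetics, nor the molecular
interpretation of `V`. Known limitations: sympodial segments and
pseudo-shoot dominance are out of scope (the simulation stops with the
primary inflorescence; vegetative axes are terminal markers, not
expanded shoots); lateral-initiation mutants (*uf*, *bl*) are outside
the two-variable model; heterozygous dosage and environmental
plasticity of allele strength are not modelled; flower-organ phenotypes
(leafy sepals) have no representation in `V`.
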