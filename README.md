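# zigzag

A deterministic kinetic simulator of primary-inflorescence development in
tomato (*Solanum lycopersicum*), for developmental biologists studying how
meristem maturation dynamics shape inflorescence architecture, and for
anyone who wants a small, fully reproducible model of cymose branching.

## The model

Every meristem carries one abstract state variable, its *vegetativeness*
`V`: high `V` means shoot (leaf-producing) identity, low `V` means flower
identity. Time is discrete in plastochrons. Four rules generate the whole
plant:

1. `V` decays once per plastochron, nonlinearly:
   `V_i = V_{i-1} − dV / V_{i-1}`.
   The decrement grows as `V` falls, so maturation accelerates — this is
   what makes a wild-type truss *finite*.
2. Two fixed thresholds split the `V` axis into identity bands: leaf
   production happens at or above the floral-transition threshold; a
   meristem whose `V` falls below the floral-commitment threshold
   irreversibly becomes a flower and initiates nothing more.
3. Once per plastochron, every active meristem produces one phytomer
   (unless committed).
4. A lateral meristem starts `ΔV` *above* the current level of its parent:
   `V′₀ = V_p + ΔV`. The upward jump followed by renewed decay gives
   trajectories their zigzag shape. A lateral born at or above the
   transition threshold is a *vegetative reversion* — a leafy axis inside
   the inflorescence.

`dV` may differ before and after the floral transition of the primary
shoot apical meristem: the pre-transition rate sets flowering time (leaf
number), the post-transition rate shapes the inflorescence. Sweeping the
post-transition `(dV, ΔV)` plane and discretising three topology metrics
(flowers before the first reversion, branching level of the transitional
meristem, number of vegetative axes) partitions the plane into eight
inflorescence *morphotypes*. Known flowering mutants (*anantha*,
*falsiflora*, *compound inflorescence*, *single flower truss*,
*jointless*, *terminating flower*) map onto parameter shifts; double
mutants are predicted by adding the single-mutant parameter vectors, with
extreme maturation rates (*an*, *fa* floor; *tmf* ceiling) masking
intermediate contributions.

## Worked example

Predict the double mutant *sft j*:

```sh
$ zigzag genotype "sft j"
{
  "classes": {
    "branching_class": "1",
    "flower_class": "1",
    "veg_class": ">=1"
  },
  "genotype": "sft j",
  "metrics": {
    "branching_level": 1,
    "censored": 0,
    "flowers_before_reversion": 1,
    "leaves_before_transition": 9,
    "no_transition": false,
    "total_flowers": 1,
    "vegetative_axes": 1
  },
  "morphotype": "5",
  ...
}
```

Read: after 9 leaves the primary meristem transitions, initiates exactly
one phytomer (`branching_level: 1`) whose lateral reverts to a vegetative
axis, and itself becomes the only flower — the robust one-flower phenotype
of this double mutant, morphotype 5 (one flower, branching 1, ≥1
vegetative axis).

Simulate the wild type and export its ontogeny:

```sh
$ zigzag simulate --out-prefix out/wt
INFO zigzag: simulated 2 meristems: 2 flowers, branching 1, 0 vegetative axes, 0 censored (morphotype 8)
$ cat out/wt.nwk
(F:10)F;
```

A finite, unbranched, reversion-free truss: the primary meristem flowers
and leaves behind a single flower-fated lateral (Newick labels: `F`
flower, `V` vegetative axis, `C` censored; branch lengths are plastochron
intervals between births). `out/wt.json` holds the full event log and
trajectories, `out/wt_trajectories.csv` the tidy zigzag table.

Scan the morphospace (1200 simulations, ~1 s):

```sh
zigzag scan --out out/morphospace.csv --heatmap out/morphospace.png
```

Library use mirrors the CLI: `ModelParams`, `simulate_plant`,
`compute_metrics`/`discretize`, `scan_morphospace`,
`parse_genotype`/`predict_phenotype`.

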