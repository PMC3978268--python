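"""Sweep of the (dV, delta_V) plane and morphotype regions.

One deterministic simulation per grid cell, varying only the
post-transition maturation rate ``dv_post`` and the lateral gain
``delta_v`` (initial level, thresholds and the pre-transition rate stay
fixed), then metric computation and morphotype labelling per cell.  The
default grid is 40 maturation-rate values on (0, 20] crossed with 30 gain
values on [0, 3] — 1200 simulations.  Exactly zero maturation rate is
excluded from the default axis (nothing ever commits there); it remains
available through :func:`zigzag.simulator.simulate_plant` directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .exceptions import MeristemCapError
from .kinetics import ModelParams
from .morphometrics import (
    InflorescenceMetrics,
    MorphotypeClass,
    UNCLASSIFIED,
    compute_metrics,
    discretize,
)
from .simulator import simulate_plant

__all__ = [
    "MorphospaceCell",
    "MorphospaceMap",
    "default_dv_values",
    "default_delta_values",
    "scan_morphospace",
    "realized_morphotypes",
    "region_of",
    "morphospace_table",
    "plot_morphospace",
]

#: CSV / DataFrame schema, bit-exact.
TABLE_COLUMNS = [
    "dv",
    "delta_v",
    "flowers",
    "branching",
    "veg_axes",
    "flower_class",
    "branching_class",
    "veg_class",
    "morphotype",
]


def default_dv_values() -> list[float]:
    """40 post-transition maturation rates: 0.5, 1.0, ..., 20.0."""
    return [round(0.5 * k, 6) for k in range(1, 41)]


def default_delta_values() -> list[float]:
    """30 lateral vegetativeness gains evenly spaced on [0, 3]."""
    return [round(3.0 * k / 29, 6) for k in range(30)]


@dataclass(frozen=True)
class MorphospaceCell:
    dv: float
    delta_v: float
    metrics: Optional[InflorescenceMetrics]
    classes: Optional[MorphotypeClass]
    capped: bool = False

    @property
    def morphotype(self) -> Optional[int]:
        return None if self.classes is None else self.classes.morphotype


@dataclass(frozen=True)
class MorphospaceMap:
    base: ModelParams
    dv_values: tuple[float, ...]
    delta_values: tuple[float, ...]
    cells: tuple[MorphospaceCell, ...]

    def __post_init__(self) -> None:
        expected = len(self.dv_values) * len(self.delta_values)
        if len(self.cells) != expected:
            raise ValueError(
                f"incomplete map: {len(self.cells)} cells for a "
                f"{len(self.dv_values)}x{len(self.delta_values)} grid"
            )


def scan_morphospace(
    base: ModelParams,
    dv_values: Optional[Sequence[float]] = None,
    delta_values: Optional[Sequence[float]] = None,
) -> MorphospaceMap:
    """Simulate every (dv_post, delta_v) cell of the grid.

    A cell whose simulation exceeds the meristem cap is flagged
    (``capped``, metrics absent) and the scan continues; the default grid
    never trips the cap.
    """
    dvs = list(default_dv_values() if dv_values is None else dv_values)
    deltas = list(default_delta_values() if delta_values is None else delta_values)
    if any(dv < 0 for dv in dvs) or any(d < 0 for d in deltas):
        raise ValueError("grid values must be non-negative")
    cells = []
    for dv in dvs:
        for delta in deltas:
            params = base.replace(dv_post=dv, delta_v=delta)
            try:
                metrics = compute_metrics(simulate_plant(params))
            except MeristemCapError:
                cells.append(MorphospaceCell(dv, delta, None, None, capped=True))
            else:
                cells.append(
                    MorphospaceCell(dv, delta, metrics, discretize(metrics))
                )
    return MorphospaceMap(
        base=base,
        dv_values=tuple(dvs),
        delta_values=tuple(deltas),
        cells=tuple(cells),
    )


def realized_morphotypes(msmap: MorphospaceMap) -> set[int]:
    """Distinct defined morphotype ids present anywhere in the map."""
    return {c.morphotype for c in msmap.cells if c.morphotype is not None}


def region_of(msmap: MorphospaceMap, morphotype: int) -> list[tuple[float, float]]:
    """All (dv, delta_v) cells labelled with the given morphotype id."""
    if morphotype not in range(1, 9):
        raise ValueError(f"unknown morphotype id: {morphotype!r} (expected 1-8)")
    return [(c.dv, c.delta_v) for c in msmap.cells if c.morphotype == morphotype]


def _cell_label(cell: MorphospaceCell) -> str:
    if cell.capped:
        return "capped"
    return cell.classes.label


def morphospace_table(msmap: MorphospaceMap) -> pd.DataFrame:
    """One row per cell with the documented column schema."""
    rows = []
    for c in msmap.cells:
        m, k = c.metrics, c.classes
        rows.append(
            {
                "dv": c.dv,
                "delta_v": c.delta_v,
                "flowers": None if m is None else m.flowers_before_reversion,
                "branching": None if m is None else m.branching_level,
                "veg_axes": None if m is None else m.vegetative_axes,
                "flower_class": None if k is None else k.flower_class,
                "branching_class": None if k is None else k.branching_class,
                "veg_class": None if k is None else k.veg_class,
                "morphotype": _cell_label(c),
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def plot_morphospace(msmap: MorphospaceMap, path: str) -> None:
    """Render the morphotype regions as a heatmap image (PNG etc.)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    dvs, deltas = msmap.dv_values, msmap.delta_values
    grid = np.zeros((len(deltas), len(dvs)))
    index = {(c.dv, c.delta_v): c for c in msmap.cells}
    for j, dv in enumerate(dvs):
        for i, delta in enumerate(deltas):
            cell = index[(dv, delta)]
            grid[i, j] = 0 if cell.morphotype is None else cell.morphotype
    fig, ax = plt.subplots(figsize=(8, 5))
    im = ax.imshow(
        grid,
        origin="lower",
        aspect="auto",
        extent=(min(dvs), max(dvs), min(deltas), max(deltas)),
        cmap=plt.get_cmap("tab10", 9),
        vmin=-0.5,
        vmax=8.5,
    )
    fig.colorbar(im, ax=ax, ticks=range(9), label=f"morphotype (0 = {UNCLASSIFIED})")
    ax.set_xlabel("dV after floral transition")
    ax.set_ylabel("delta V at lateral initiation")
    ax.set_title("Inflorescence morphospace")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
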