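"""Writers: ontogeny JSON, Newick topology, trajectory and morphospace CSV.

All writers are bit-exact given identical inputs (no timestamps, sorted
keys, LF line endings, '.' decimal separator) so byte-identical reruns
can be asserted by hashing.  Every output embeds or is accompanied by the
full parameter set that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import dendropy

from .morphospace import MorphospaceMap, morphospace_table
from .simulator import Fate, Ontogeny, vegetativeness_trajectories

__all__ = [
    "ontogeny_to_dict",
    "write_ontogeny_json",
    "ontogeny_to_newick",
    "write_newick",
    "write_trajectories_csv",
    "write_morphospace_csv",
    "write_params_json",
]

# Newick node labels by terminal fate.
_FATE_LABEL = {
    Fate.FLOWER: "F",
    Fate.VEGETATIVE_AXIS: "V",
    Fate.CENSORED: "C",
    Fate.ACTIVE: "A",  # never present in a finished simulation
}


def ontogeny_to_dict(ontogeny: Ontogeny) -> dict:
    """JSON-ready representation: params echo, meristem registry, event log.

    Ticks are 0-based plastochron indices; tree depth is measured in
    generations (root = 0); trajectories are ordered (tick, level) pairs
    starting at birth.
    """
    return {
        "params": ontogeny.params.to_dict(),
        "transition_tick": ontogeny.transition_tick,
        "final_tick": ontogeny.final_tick,
        "meristems": [
            {
                "id": m.id,
                "parent_id": m.parent_id,
                "birth_tick": m.birth_tick,
                "birth_level": m.birth_level,
                "identity_at_birth": m.identity_at_birth.value,
                "fate": m.fate.value,
                "generation": m.generation,
                "children": list(m.children),
                "trajectory": [[t, lv] for t, lv in m.trajectory],
            }
            for m in ontogeny.meristems.values()
        ],
        "events": [[e.tick, e.meristem_id, e.kind.value] for e in ontogeny.events],
    }


def write_ontogeny_json(ontogeny: Ontogeny, path: str | Path) -> None:
    payload = json.dumps(ontogeny_to_dict(ontogeny), indent=2, sort_keys=True)
    Path(path).write_text(payload + "\n", encoding="utf-8")


def ontogeny_to_newick(ontogeny: Ontogeny) -> str:
    """Inflorescence tree as Newick text.

    Node labels encode the terminal fate (F flower, V vegetative axis,
    C censored); branch lengths are plastochron intervals between the
    birth of a meristem and the birth of its parent.  Inflorescences are
    not phylogenies, but Newick keeps the topology exchangeable with
    standard tree tooling.
    """
    tree = dendropy.Tree()

    def attach(node: dendropy.Node, meristem_id: int) -> None:
        m = ontogeny.meristems[meristem_id]
        node.label = _FATE_LABEL[m.fate]
        parent = (
            ontogeny.meristems[m.parent_id] if m.parent_id is not None else None
        )
        node.edge.length = (
            m.birth_tick - parent.birth_tick if parent is not None else None
        )
        for child_id in m.children:
            attach(node.new_child(), child_id)

    attach(tree.seed_node, ontogeny.root.id)
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        suppress_leaf_node_labels=False,
    )
    return text.strip() + "\n"


def write_newick(ontogeny: Ontogeny, path: str | Path) -> None:
    Path(path).write_text(ontogeny_to_newick(ontogeny), encoding="utf-8")


def write_trajectories_csv(ontogeny: Ontogeny, path: str | Path) -> None:
    df = vegetativeness_trajectories(ontogeny)
    df.to_csv(path, index=False, lineterminator="\n")


def write_morphospace_csv(msmap: MorphospaceMap, path: str | Path) -> None:
    morphospace_table(msmap).to_csv(path, index=False, lineterminator="\n")


def write_params_json(params, path: str | Path, extra: dict | None = None) -> None:
    """Provenance echo written alongside every CLI output."""
    payload = {"params": params.to_dict()}
    if extra:
        payload.update(extra)
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
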