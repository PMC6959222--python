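"""Shortlisting rules over activity predictions.

Two selection rules applied downstream of the activity model: keep
mechanisms of action supported by enough distinct molecules predicted
active with high confidence, and keep plants with at least one molecule
confidently predicted for multiple mechanisms plus a therapeutic effect.
Both comparisons against the Pa cutoff are strict (Pa must exceed it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from netprev.revpharm.activity import Prediction

DEFAULT_PA_MIN = 0.5
DEFAULT_MIN_MOLECULES = 5


def select_moas(
    predictions: Iterable[Prediction],
    pa_min: float = DEFAULT_PA_MIN,
    min_molecules: int = DEFAULT_MIN_MOLECULES,
) -> list[tuple[str, int]]:
    """Activities predicted with Pa > ``pa_min`` for at least
    ``min_molecules`` distinct molecules, with their molecule counts.

    ``min_molecules=1`` gives the permissive screen used for targets with
    already-known disease links; the default of 5 is the stricter rule
    for nominating new mechanisms.  Sorted by count (descending), then
    activity name.
    """
    support: dict[str, set[str]] = {}
    for p in predictions:
        if p.Pa > pa_min:
            support.setdefault(p.activity, set()).add(p.mol_id)
    kept = [(a, len(mols)) for a, mols in support.items() if len(mols) >= min_molecules]
    return sorted(kept, key=lambda t: (-t[1], t[0]))


@dataclass(frozen=True)
class PlantSelection:
    plant: str
    molecules: tuple[str, ...]
    matched_moas: tuple[str, ...]
    matched_effects: tuple[str, ...]


def select_dual_action_plants(
    predictions: Iterable[Prediction],
    plant_map: Mapping[str, Sequence[str]],
    moa_set: Iterable[str],
    effect_set: Iterable[str],
    pa_min: float = DEFAULT_PA_MIN,
) -> list[PlantSelection]:
    """Plants with a molecule confidently active for dual mechanisms and a
    therapeutic effect.

    A plant qualifies when at least one of its molecules has Pa >
    ``pa_min`` simultaneously for two or more activities in ``moa_set``
    and for at least one activity in ``effect_set``.  ``plant_map`` maps
    plant -> its molecule ids.  All qualifying molecules and the union of
    their matched activities are reported per plant.
    """
    moa_set, effect_set = set(moa_set), set(effect_set)
    per_mol: dict[str, set[str]] = {}
    for p in predictions:
        if p.Pa > pa_min:
            per_mol.setdefault(p.mol_id, set()).add(p.activity)
    out = []
    for plant in sorted(plant_map):
        qualifying: list[str] = []
        moas: set[str] = set()
        effects: set[str] = set()
        for mol_id in plant_map[plant]:
            hits = per_mol.get(mol_id, set())
            mol_moas = hits & moa_set
            mol_effects = hits & effect_set
            if len(mol_moas) >= 2 and mol_effects:
                qualifying.append(mol_id)
                moas |= mol_moas
                effects |= mol_effects
        if qualifying:
            out.append(
                PlantSelection(
                    plant=plant,
                    molecules=tuple(sorted(qualifying)),
                    matched_moas=tuple(sorted(moas)),
                    matched_effects=tuple(sorted(effects)),
                )
            )
    return out
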