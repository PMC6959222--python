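"""Multilevel neighbourhoods of atoms (MNA) descriptors.

Each atom contributes one descriptor string per level.  The level-0
descriptor is the atom label — element symbol plus attached-hydrogen
count (``CH3``, ``OH``, ``C``).  The level-n descriptor prepends the
atom's label to the parenthesized, lexicographically sorted level-(n-1)
descriptors of its neighbours.  Bond orders are ignored; hydrogens are
folded into the labels rather than treated as graph nodes.  The multiset
of per-atom strings is therefore invariant to atom reindexing, which is
what makes it usable as a canonical substructure fingerprint.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from rdkit import Chem

from netprev.revpharm.molecules import Molecule

MAX_LEVEL = 4


@dataclass(frozen=True)
class DescriptorSet:
    """Multiset of canonical atom-neighbourhood strings at one level."""

    level: int
    descriptors: tuple[str, ...]  # sorted, with multiplicity

    def counter(self) -> Counter[str]:
        return Counter(self.descriptors)

    def distinct(self) -> frozenset[str]:
        return frozenset(self.descriptors)

    def __len__(self) -> int:
        return len(self.descriptors)


def atom_label(atom: Chem.Atom, mark_rings: bool = False) -> str:
    """Element symbol plus attached-hydrogen count; optional ring mark."""
    h = atom.GetTotalNumHs()
    label = atom.GetSymbol()
    if h == 1:
        label += "H"
    elif h > 1:
        label += f"H{h}"
    if mark_rings and atom.IsInRing():
        label = "@" + label
    return label


def mna_descriptors(molecule: Molecule | Chem.Mol, level: int, mark_rings: bool = False) -> DescriptorSet:
    """Per-atom MNA descriptor multiset at the given level (0-4)."""
    if not 0 <= level <= MAX_LEVEL:
        raise ValueError(f"level must be in [0, {MAX_LEVEL}], got {level}")
    mol = molecule.mol if isinstance(molecule, Molecule) else molecule
    if mol is None:
        raise ValueError("molecule has no parsed structure")
    labels = [atom_label(a, mark_rings) for a in mol.GetAtoms()]
    neighbours = [
        sorted(b.GetIdx() for b in a.GetNeighbors()) for a in mol.GetAtoms()
    ]
    current = list(labels)
    for _ in range(level):
        current = [
            labels[i] + "(" + ",".join(sorted(current[j] for j in neighbours[i])) + ")"
            for i in range(len(labels))
        ]
    return DescriptorSet(level=level, descriptors=tuple(sorted(current)))


def mna_profile(
    molecule: Molecule | Chem.Mol, max_level: int, mark_rings: bool = False
) -> frozenset[str]:
    """Distinct descriptors pooled over levels 0..``max_level``.

    Deeper descriptors are more specific but rarer; pooling all levels
    lets shared shallow neighbourhoods carry signal even when a deep
    environment is unique to one molecule.  Levels cannot collide as
    strings (level-n descriptors always carry n nested parentheses).
    """
    out: set[str] = set()
    for lvl in range(max_level + 1):
        out |= set(mna_descriptors(molecule, lvl, mark_rings).descriptors)
    return frozenset(out)
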