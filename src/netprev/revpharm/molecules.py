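"""Molecule handling and the structure eligibility filter.

Structures come in as SMILES or SDF (2D) via RDKit.  The eligibility
filter keeps single electroneutral organic structures with molecular
weight between 50 and 1250 Da and at least three carbon atoms; salts and
other multi-component records fail the single-structure rule (no salt
stripping is attempted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")

MW_MIN = 50.0
MW_MAX = 1250.0
MIN_CARBONS = 3


@dataclass
class Molecule:
    """A 2D structure with an identifier and optional plant provenance."""

    mol_id: str
    mol: Chem.Mol | None
    smiles: str = ""
    source_plant_ids: tuple[str, ...] = ()

    @classmethod
    def from_smiles(
        cls, mol_id: str, smiles: str, source_plant_ids: Sequence[str] = ()
    ) -> "Molecule":
        mol = Chem.MolFromSmiles(smiles)
        return cls(
            mol_id=mol_id,
            mol=mol,
            smiles=smiles,
            source_plant_ids=tuple(source_plant_ids),
        )

    @property
    def parsable(self) -> bool:
        return self.mol is not None


@dataclass(frozen=True)
class Rejection:
    mol_id: str
    reason: str


def filter_structures(
    molecules: Iterable[Molecule],
) -> tuple[list[Molecule], list[Rejection]]:
    """Apply the eligibility rules in order; label each rejection with the
    first failed rule.

    Rules, in order: parsable; exactly one connected component; net formal
    charge zero; 50 <= MW <= 1250 Da (standard atomic masses, hydrogens
    included); at least three carbon atoms.
    """
    eligible: list[Molecule] = []
    rejected: list[Rejection] = []
    for m in molecules:
        reason = rejection_reason(m)
        if reason is None:
            eligible.append(m)
        else:
            rejected.append(Rejection(mol_id=m.mol_id, reason=reason))
    return eligible, rejected


def rejection_reason(m: Molecule) -> str | None:
    """First failed eligibility rule, or None if the molecule is eligible."""
    if m.mol is None:
        return "unparsable structure"
    if len(Chem.GetMolFrags(m.mol)) != 1:
        return "not a single structure (multiple components)"
    if Chem.GetFormalCharge(m.mol) != 0:
        return "not electroneutral (nonzero net formal charge)"
    mw = Descriptors.MolWt(m.mol)
    if not (MW_MIN <= mw <= MW_MAX):
        return f"molecular weight {mw:.2f} Da outside [{MW_MIN:g}, {MW_MAX:g}]"
    n_carbon = sum(1 for a in m.mol.GetAtoms() if a.GetSymbol() == "C")
    if n_carbon < MIN_CARBONS:
        return f"only {n_carbon} carbon atoms (< {MIN_CARBONS})"
    return None


def read_smiles_file(path: str | Path) -> list[Molecule]:
    """Read a SMILES file: ``smiles  mol_id  [plant1,plant2,...]`` per line."""
    out = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"mol{lineno}"
            plants: tuple[str, ...] = ()
            if len(parts) > 2 and parts[2]:
                plants = tuple(parts[2].split(","))
            out.append(Molecule.from_smiles(mol_id, smiles, plants))
    return out


def write_smiles_file(molecules: Iterable[Molecule], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for m in molecules:
            plants = ",".join(m.source_plant_ids)
            fh.write(f"{m.smiles}\t{m.mol_id}\t{plants}\n")


def read_sdf(path: str | Path) -> list[Molecule]:
    """Read molecules from an SD file; the title line (or ``_Name``) is the id."""
    out = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            out.append(Molecule(mol_id=f"sdf{i}", mol=None))
            continue
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf{i}"
        plants: tuple[str, ...] = ()
        if mol.HasProp("plants"):
            plants = tuple(p for p in mol.GetProp("plants").split(",") if p)
        out.append(
            Molecule(mol_id=mol_id, mol=mol, smiles=Chem.MolToSmiles(mol), source_plant_ids=plants)
        )
    return out


def write_sdf(molecules: Iterable[Molecule], path: str | Path) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for m in molecules:
            if m.mol is None:
                continue
            mol = Chem.Mol(m.mol)
            mol.SetProp("_Name", m.mol_id)
            if m.source_plant_ids:
                mol.SetProp("plants", ",".join(m.source_plant_ids))
            writer.write(mol)
    finally:
        writer.close()
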