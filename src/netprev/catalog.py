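"""Curated gene-disease and drug-target catalogues.

This module loads the curated evidence tables that seed the network
analysis: gene-disease association rows (gene symbol, species, type of
molecular alteration, and its relationship to the disease) and
mechanism-of-action rows linking approved drugs to protein targets.
It also implements the seed-set construction: merging disease-associated
genes with drug-target genes into a single provenance-tracked seed set.
"""

from __future__ import annotations

import csv
import enum
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class Species(str, enum.Enum):
    """Species in which a gene-disease association was observed."""

    HUMAN = "h"
    RAT = "r"
    MOUSE = "m"


class Alteration(str, enum.Enum):
    """Closed vocabulary of molecular alterations linking a gene to disease."""

    MUTATION = "mutation"
    POLYMORPHISM = "polymorphism"
    EXPRESSION_UP = "expression_up"
    EXPRESSION_DOWN = "expression_down"
    ACTIVITY_UP = "activity_up"
    ACTIVITY_DOWN = "activity_down"
    PHOSPHORYLATION_UP = "phosphorylation_up"
    ACTIVATION = "activation"
    INHIBITION = "inhibition"
    ABSENCE = "absence"
    ABNORMAL_FOLDING = "abnormal_folding"
    DECREASED_PROCESSING = "decreased_processing"


class Relationship(str, enum.Enum):
    """How an alteration relates to the disease."""

    CAUSES = "causes"
    MAY_PREVENT = "may_prevent"
    CORRELATES = "correlates"


class DrugAction(str, enum.Enum):
    AGONIST = "agonist"
    ANTAGONIST = "antagonist"
    INHIBITOR = "inhibitor"
    ACTIVATOR = "activator"
    OTHER = "other"


# Free-text phrases found in curated tables, mapped onto the closed enums at
# ingest.  Unknown phrases are load errors, never silently "other".
_ALTERATION_PHRASES: dict[str, Alteration] = {
    "mutation": Alteration.MUTATION,
    "polymorphism": Alteration.POLYMORPHISM,
    "abnormal folding": Alteration.ABNORMAL_FOLDING,
    "absence": Alteration.ABSENCE,
    "decreased processing": Alteration.DECREASED_PROCESSING,
    "activation": Alteration.ACTIVATION,
    "inhibition": Alteration.INHIBITION,
    "up expression": Alteration.EXPRESSION_UP,
    "↑ expression": Alteration.EXPRESSION_UP,
    "increased expression": Alteration.EXPRESSION_UP,
    "down expression": Alteration.EXPRESSION_DOWN,
    "↓ expression": Alteration.EXPRESSION_DOWN,
    "decreased expression": Alteration.EXPRESSION_DOWN,
    "increased activity": Alteration.ACTIVITY_UP,
    "up activity": Alteration.ACTIVITY_UP,
    "decreased activity": Alteration.ACTIVITY_DOWN,
    "down activity": Alteration.ACTIVITY_DOWN,
    "increased phosphorylation": Alteration.PHOSPHORYLATION_UP,
    "up phosphorylation": Alteration.PHOSPHORYLATION_UP,
}
_ALTERATION_PHRASES.update({a.value: a for a in Alteration})

_RELATIONSHIP_PHRASES: dict[str, Relationship] = {
    "causes": Relationship.CAUSES,
    "may prevent": Relationship.MAY_PREVENT,
    "may_prevent": Relationship.MAY_PREVENT,
    "correlates": Relationship.CORRELATES,
}

# Alterations counted as "increase" when extending the actionable set with
# correlative evidence.
INCREASE_ALTERATIONS = frozenset(
    {Alteration.EXPRESSION_UP, Alteration.ACTIVITY_UP, Alteration.PHOSPHORYLATION_UP}
)

ASSOCIATION_COLUMNS = ("gene", "disease", "species", "alteration", "relationship", "evidence_ref")
DRUG_TABLE_COLUMNS = ("mechanism", "uniprot_id", "rank", "drug")

NO_DRUG_MARKERS = frozenset({"", "-", "—"})


class SchemaError(ValueError):
    """A table is missing required columns."""


class RowParseError(ValueError):
    """A table row holds a value outside the closed vocabularies."""

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


@dataclass(frozen=True)
class GeneDiseaseAssociation:
    """One curated evidence row linking a gene to the disease."""

    gene_symbol: str
    disease: str
    species: tuple[Species, ...]
    alteration: tuple[Alteration, ...]
    relationship: Relationship
    evidence_ref: str = ""

    def __post_init__(self):
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")
        object.__setattr__(self, "gene_symbol", self.gene_symbol.upper())


@dataclass(frozen=True)
class DrugTargetRecord:
    """One (drug, target, action) row from a mechanism-of-action table."""

    drug_name: str
    target_gene: str
    action: DrugAction
    effect: str = ""

    def __post_init__(self):
        if not self.target_gene:
            raise ValueError("target_gene must be non-empty")


@dataclass(frozen=True)
class MechanismRow:
    """One mechanism-of-action row: a typed action on a protein target."""

    mechanism: str
    target: str
    rank: int | None
    drugs: tuple[str, ...]

    @property
    def action(self) -> DrugAction:
        return action_from_mechanism(self.mechanism)


@dataclass
class SeedGeneSet:
    """Union of disease-associated and drug-target genes, with provenance."""

    genes: frozenset[str]
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def overlap(self) -> frozenset[str]:
        """Genes carrying more than one source tag."""
        return frozenset(g for g, tags in self.provenance.items() if len(set(tags)) > 1)


def _parse_species(cell: str, row_index: int) -> tuple[Species, ...]:
    out = []
    for tok in cell.replace(";", ",").split(","):
        tok = tok.strip().lower()
        if not tok:
            continue
        try:
            out.append(Species(tok))
        except ValueError:
            raise RowParseError(row_index, f"unknown species code {tok!r}") from None
    if not out:
        raise RowParseError(row_index, "empty species field")
    return tuple(out)


def _parse_alterations(cell: str, row_index: int) -> tuple[Alteration, ...]:
    out = []
    for tok in cell.split(";"):
        tok = tok.strip().lower()
        if not tok:
            continue
        alt = _ALTERATION_PHRASES.get(tok)
        if alt is None:
            raise RowParseError(row_index, f"unknown alteration phrase {tok!r}")
        out.append(alt)
    if not out:
        raise RowParseError(row_index, "empty alteration field")
    return tuple(out)


def _parse_relationship(cell: str, row_index: int) -> Relationship:
    tok = cell.strip().lower()
    # Accept both bare tokens and disease-qualified phrases ("causes VaD").
    for phrase, rel in _RELATIONSHIP_PHRASES.items():
        if tok == phrase or tok.startswith(phrase + " "):
            return rel
    raise RowParseError(row_index, f"unknown relationship phrase {cell!r}")


def load_associations(path: str | Path) -> list[GeneDiseaseAssociation]:
    """Load a gene-disease association table (TSV).

    Expects the header ``gene  disease  species  alteration  relationship
    evidence_ref``.  Gene symbols are uppercased; species, alteration and
    relationship cells are mapped onto the closed vocabularies, with
    unparsable values rejected with their row number.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            warnings.warn(f"{path}: empty file, no associations loaded")
            return []
        missing = set(ASSOCIATION_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise SchemaError(f"{path}: missing columns {sorted(missing)}")
        records = []
        for i, row in enumerate(reader, start=1):
            records.append(
                GeneDiseaseAssociation(
                    gene_symbol=row["gene"].strip(),
                    disease=row["disease"].strip(),
                    species=_parse_species(row["species"], i),
                    alteration=_parse_alterations(row["alteration"], i),
                    relationship=_parse_relationship(row["relationship"], i),
                    evidence_ref=row["evidence_ref"].strip(),
                )
            )
    if not records:
        warnings.warn(f"{path}: header only, no associations loaded")
    return records


def load_drug_table(path: str | Path) -> list[MechanismRow]:
    """Load a mechanism-of-action table (TSV).

    Expects the header ``mechanism  uniprot_id  rank  drug`` with
    semicolon-separated drug lists; an em-dash (or empty cell) marks a
    target with no approved drug.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        missing = set(DRUG_TABLE_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise SchemaError(f"{path}: missing columns {sorted(missing)}")
        rows = []
        for i, row in enumerate(reader, start=1):
            cell = row["drug"].strip()
            drugs: tuple[str, ...]
            if cell in NO_DRUG_MARKERS:
                drugs = ()
            else:
                drugs = tuple(d.strip() for d in cell.split(";") if d.strip())
            rank_cell = row["rank"].strip()
            try:
                rank = int(rank_cell) if rank_cell else None
            except ValueError:
                raise RowParseError(i, f"non-integer rank {rank_cell!r}") from None
            rows.append(
                MechanismRow(
                    mechanism=row["mechanism"].strip(),
                    target=row["uniprot_id"].strip(),
                    rank=rank,
                    drugs=drugs,
                )
            )
    return rows


def action_from_mechanism(mechanism: str) -> DrugAction:
    """Infer the typed drug action from a mechanism-of-action name."""
    low = mechanism.lower()
    for word, action in (
        ("inhibitor", DrugAction.INHIBITOR),
        ("antagonist", DrugAction.ANTAGONIST),
        ("agonist", DrugAction.AGONIST),
        ("activator", DrugAction.ACTIVATOR),
    ):
        if word in low:
            return action
    return DrugAction.OTHER


def drug_target_records(rows: Iterable[MechanismRow]) -> list[DrugTargetRecord]:
    """Expand mechanism rows into one record per (drug, target, action)."""
    out = []
    for row in rows:
        for drug in row.drugs:
            out.append(
                DrugTargetRecord(
                    drug_name=drug,
                    target_gene=row.target,
                    action=row.action,
                    effect=row.mechanism,
                )
            )
    return out


def count_drug_entries(records: Sequence[DrugTargetRecord]) -> int:
    """Count drug entries once per (drug, target) row.

    A drug listed under two targets counts twice; targets without an
    approved drug contribute nothing.
    """
    return sum(1 for _ in records)


def merge_seed_genes(
    association_genes: Iterable[str],
    drug_target_genes: Iterable[str],
    tags: tuple[str, str] = ("disease_association", "drug_target"),
) -> SeedGeneSet:
    """Union of disease-associated and drug-target gene symbols.

    Symbols are matched case-insensitively (uppercased).  The returned set
    carries per-gene provenance tags so that the overlap between the two
    sources is explicit rather than implied by arithmetic.
    """
    a = {g.upper() for g in association_genes}
    b = {g.upper() for g in drug_target_genes}
    provenance: dict[str, list[str]] = {}
    for g in a:
        provenance.setdefault(g, []).append(tags[0])
    for g in b:
        provenance.setdefault(g, []).append(tags[1])
    return SeedGeneSet(genes=frozenset(a | b), provenance=provenance)


def filter_direct(
    associations: Sequence[GeneDiseaseAssociation],
) -> list[GeneDiseaseAssociation]:
    """Keep rows whose relationship is causal or preventive (not merely
    correlative), preserving input order."""
    keep = {Relationship.CAUSES, Relationship.MAY_PREVENT}
    return [a for a in associations if a.relationship in keep]


def count_by_relationship(
    associations: Sequence[GeneDiseaseAssociation],
) -> dict[Relationship, int]:
    """Number of distinct gene symbols per relationship value."""
    genes: dict[Relationship, set[str]] = {rel: set() for rel in Relationship}
    for a in associations:
        genes[a.relationship].add(a.gene_symbol)
    return {rel: len(g) for rel, g in genes.items()}


def select_actionable(associations: Sequence[GeneDiseaseAssociation]) -> set[str]:
    """Genes worth screening pharmacologically.

    The union of (a) genes with a direct causal/preventive relationship and
    (b) genes merely correlated with the disease but through an *increase*
    in expression, activity or phosphorylation — the alterations a blocking
    ligand could plausibly counteract.
    """
    out: set[str] = set()
    for a in associations:
        if a.relationship in (Relationship.CAUSES, Relationship.MAY_PREVENT):
            out.add(a.gene_symbol)
        elif a.relationship is Relationship.CORRELATES and any(
            alt in INCREASE_ALTERATIONS for alt in a.alteration
        ):
            out.add(a.gene_symbol)
    return out


def packaged_fixture(name: str) -> Path:
    """Path to a packaged data table (``table1.tsv`` or ``table2.tsv``)."""
    return Path(str(resources.files("netprev").joinpath("data", name)))
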